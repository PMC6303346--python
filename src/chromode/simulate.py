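"""Seeded synthetic-data generator with planted ground truth.

Emulates the structure of a two-factor ChIP-seq / two-genotype RNA-seq
study: a genome of uniformly spaced genes; sharp transcription-factor
peaks planted at a subset of promoters (factor B co-occupying a tunable
fraction of factor-A sites); an activating histone mark in 2-kb promoter
domains and a repressive mark in 10-kb domains over silenced genes; tag
libraries with uniform Poisson background and fold-enriched planted
regions; and genotype-dependent expression with multiplicative replicate
noise. Gene classes:

activated_target
    factor-A bound, active-mark domain, expression drops by
    ``activated_effect`` in the knockout.
repressed_target
    factor-A bound, repressive-mark domain (low baseline expression),
    expression rises by ``repressed_effect`` in the knockout.
neutral
    everything else; a subset carries factor-B-only peaks with active
    marks so that solo-B sites exist.

A gene is never both active-marked and repressive-marked, so the planted
chromatin mode of every factor-A peak is unambiguous. Every artifact is a
deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    TagLibrary,
    write_bed,
    write_gene_annotation,
    write_tags_bed,
)
from .gsea import GeneSet, write_gmt


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    min_tss_spacing: int = 25_000
    frac_tfA_bound_promoters: float = 0.4
    frac_coB_given_A: float = 0.45
    frac_me3_repressed_genes: float = 0.15   # of factor-A-bound genes
    frac_tfB_extra_promoters: float = 0.15   # of non-A genes: solo-B sites
    peak_fold_enrichment: float = 8.0
    domain_fold_enrichment: float = 8.0
    tf_peak_width: int = 300
    ac_domain_width: int = 2_000
    me3_domain_width: int = 10_000
    tags_per_library: int = 200_000
    n_replicates: int = 2
    baseline_log2_fpkm_mean: float = 4.0
    baseline_log2_fpkm_sd: float = 1.5
    activated_effect: float = 4.0   # fold-down in KO
    repressed_effect: float = 4.0   # fold-up in KO
    replicate_cv: float = 0.2

    def __post_init__(self) -> None:
        for name in ("frac_tfA_bound_promoters", "frac_coB_given_A",
                     "frac_me3_repressed_genes", "frac_tfB_extra_promoters"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("peak_fold_enrichment", "domain_fold_enrichment",
                     "activated_effect", "repressed_effect"):
            if not getattr(self, name) > 1:
                raise ValueError(f"{name} must be > 1")
        if self.tags_per_library < 10_000:
            raise ValueError("tags_per_library must be >= 1e4")


@dataclass
class TruthManifest:
    """Planted ground truth: per-gene class, per-library planted intervals,
    and per-gene expression effect (KO/WT fold)."""

    gene_class: dict[str, str] = field(default_factory=dict)
    planted_intervals: dict[str, list[dict]] = field(default_factory=dict)
    expression_effect: dict[str, float] = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.gene_class.items() if c == cls)

    def intervals_for(self, library: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(d["chrom"], d["start"], d["end"], name=d.get("gene_id", ""))
            for d in self.planted_intervals.get(library, [])
        ]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "gene_class": self.gene_class,
                "planted_intervals": self.planted_intervals,
                "expression_effect": self.expression_effect,
            },
            indent=1,
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        data = json.loads(Path(path).read_text())
        validate_truth(data)
        return cls(**data)


def validate_truth(data: dict) -> None:
    """Schema check for a truth-manifest JSON object."""
    for key in ("gene_class", "planted_intervals", "expression_effect"):
        if key not in data:
            raise ValueError(f"truth manifest missing key {key!r}")
    valid = {"activated_target", "repressed_target", "neutral"}
    for gid, c in data["gene_class"].items():
        if c not in valid:
            raise ValueError(f"gene {gid}: invalid class {c!r}")
    for lib, ivs in data["planted_intervals"].items():
        for d in ivs:
            if not {"chrom", "start", "end"} <= set(d):
                raise ValueError(f"library {lib}: interval missing fields: {d}")
            if not 0 <= d["start"] < d["end"]:
                raise ValueError(f"library {lib}: bad interval coordinates {d}")
    for gid, f in data["expression_effect"].items():
        if not f > 0:
            raise ValueError(f"gene {gid}: non-positive effect {f}")


def simulate_annotation(config: SimConfig) -> tuple[list[GeneModel], GenomeLayout]:
    """Uniformly placed genes with a minimal TSS spacing, random strands."""
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    margin = 30_000  # keep domains and signal windows inside the chromosome
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    genes: list[GeneModel] = []
    idx = 0
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        usable = config.chrom_length - 2 * margin - (n_c - 1) * config.min_tss_spacing
        if n_c > 0 and usable <= 0:
            raise ValueError("n_genes too large for genome at the required spacing")
        if n_c == 0:
            continue
        slack = np.sort(rng.uniform(0, usable, n_c))
        tss = (margin + slack + np.arange(n_c) * config.min_tss_spacing).astype(int)
        for t in tss:
            idx += 1
            gid = f"g{idx:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(5_000, 20_000))
            if strand == "+":
                tes = min(int(t) + length, config.chrom_length)
                genes.append(GeneModel(gid, chrom, "+", int(t), tes))
            else:
                tes = max(int(t) - length, 0)
                genes.append(GeneModel(gid, chrom, "-", int(t), tes))
    return genes, layout


def assign_classes(config: SimConfig, genes: list[GeneModel]) -> TruthManifest:
    """Plant gene classes and the corresponding peak/domain intervals."""
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthManifest()
    ids = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}
    n_a = round(config.frac_tfA_bound_promoters * len(ids))
    a_bound = sorted(rng.choice(ids, size=n_a, replace=False))
    a_set = set(a_bound)
    n_rep = round(config.frac_me3_repressed_genes * n_a)
    repressed = sorted(rng.choice(a_bound, size=n_rep, replace=False))
    rep_set = set(repressed)
    co_b = {g for g in a_bound if rng.random() < config.frac_coB_given_A}
    non_a = [g for g in ids if g not in a_set]
    b_solo = {
        g for g in non_a if rng.random() < config.frac_tfB_extra_promoters
    }

    for gid in ids:
        if gid in rep_set:
            truth.gene_class[gid] = "repressed_target"
        elif gid in a_set:
            truth.gene_class[gid] = "activated_target"
        else:
            truth.gene_class[gid] = "neutral"

    def plant(lib: str, gid: str, width: int) -> None:
        g = by_id[gid]
        half = width // 2
        start = max(0, g.tss - half)
        truth.planted_intervals.setdefault(lib, []).append(
            {"chrom": g.chrom, "start": int(start), "end": int(start + width),
             "gene_id": gid}
        )

    for gid in a_bound:
        plant("tfA", gid, config.tf_peak_width)
        if gid in co_b:
            plant("tfB", gid, config.tf_peak_width)
        if gid in rep_set:
            plant("me3", gid, config.me3_domain_width)
        else:
            plant("ac", gid, config.ac_domain_width)
    for gid in sorted(b_solo):
        plant("tfB", gid, config.tf_peak_width)
        plant("ac", gid, config.ac_domain_width)

    for gid in ids:
        if truth.gene_class[gid] == "activated_target":
            truth.expression_effect[gid] = 1.0 / config.activated_effect
        elif truth.gene_class[gid] == "repressed_target":
            truth.expression_effect[gid] = config.repressed_effect
        else:
            truth.expression_effect[gid] = 1.0
    return truth


def sample_tag_library(
    rng: np.random.Generator,
    layout: GenomeLayout,
    enriched: list[tuple[str, int, int, float]],
    total_tags: int,
) -> TagLibrary:
    """Sample tag positions from a piecewise-constant intensity: baseline 1
    everywhere, ``fold`` inside each enriched interval. The expected total
    is ``total_tags``."""
    chroms = list(layout.lengths)
    lengths = np.array([layout.lengths[c] for c in chroms], dtype=float)
    extra_mass = np.zeros(len(chroms))
    per_chrom_enriched: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for chrom, start, end, fold in enriched:
        per_chrom_enriched[chrom].append((start, end, fold))
        extra_mass[chroms.index(chrom)] += (fold - 1.0) * (end - start)
    mass = lengths + extra_mass
    n_total = rng.poisson(total_tags)
    counts = rng.multinomial(n_total, mass / mass.sum())
    tags: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(chroms):
        regions = per_chrom_enriched[chrom]
        seg_mass = [lengths[ci]] + [(f - 1.0) * (e - s) for s, e, f in regions]
        seg_mass = np.asarray(seg_mass, dtype=float)
        seg_counts = rng.multinomial(counts[ci], seg_mass / seg_mass.sum())
        pos = [rng.integers(0, int(lengths[ci]), seg_counts[0])]
        for (s, e, _f), k in zip(regions, seg_counts[1:]):
            pos.append(rng.integers(s, e, k))
        tags[chrom] = np.sort(np.concatenate(pos)) if pos else np.empty(0, np.int64)
    return TagLibrary(tags)


def simulate_chip(
    config: SimConfig, truth: TruthManifest, layout: GenomeLayout
) -> dict[str, TagLibrary]:
    """Tag libraries for factor A, factor B, both marks, and input.

    Input is pure uniform background; each ChIP library is background plus
    its planted intervals at the configured fold enrichment.
    """
    rng = np.random.default_rng(config.seed + 2)
    folds = {
        "tfA": config.peak_fold_enrichment,
        "tfB": config.peak_fold_enrichment,
        "me3": config.domain_fold_enrichment,
        "ac": config.domain_fold_enrichment,
    }
    libs: dict[str, TagLibrary] = {}
    for name in ("tfA", "tfB", "me3", "ac"):
        enriched = [
            (d["chrom"], d["start"], d["end"], folds[name])
            for d in truth.planted_intervals.get(name, [])
        ]
        libs[name] = sample_tag_library(rng, layout, enriched, config.tags_per_library)
    libs["input"] = sample_tag_library(rng, layout, [], config.tags_per_library)
    return libs


def simulate_expression(
    config: SimConfig, truth: TruthManifest
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table (genes x samples) and its design table.

    Baselines are log-normal; repressed targets start 3 log2 units below
    and activated targets 1 log2 unit above the neutral mean (a silenced
    locus is lowly expressed in the wild type, an activated one highly).
    Knockout samples multiply the baseline by the planted effect; replicate
    noise is multiplicative log-normal at ``replicate_cv``.
    """
    rng = np.random.default_rng(config.seed + 3)
    gene_ids = sorted(truth.gene_class)
    shift = {"activated_target": 1.0, "repressed_target": -3.0, "neutral": 0.0}
    base_log2 = np.array(
        [
            rng.normal(
                config.baseline_log2_fpkm_mean + shift[truth.gene_class[g]],
                config.baseline_log2_fpkm_sd,
            )
            for g in gene_ids
        ]
    )
    baseline = 2.0 ** base_log2
    effect = np.array([truth.expression_effect[g] for g in gene_ids])
    sigma = np.sqrt(np.log1p(config.replicate_cv ** 2))
    cols, data, meta = [], [], []
    for genotype in ("WT", "KO"):
        mean = baseline * effect if genotype == "KO" else baseline
        for rep in range(1, config.n_replicates + 1):
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, len(gene_ids))
            name = f"{genotype}_{rep}"
            cols.append(name)
            data.append(mean * noise)
            meta.append({"sample": name, "genotype": genotype, "replicate": rep})
    fpkm = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    fpkm.index.name = "gene_id"
    return fpkm, pd.DataFrame(meta)


@dataclass
class SimResult:
    config: SimConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    truth: TruthManifest
    libraries: dict[str, TagLibrary]
    fpkm: pd.DataFrame
    design: pd.DataFrame


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: annotation, classes, ChIP libraries, expression."""
    genes, layout = simulate_annotation(config)
    truth = assign_classes(config, genes)
    libs = simulate_chip(config, truth, layout)
    fpkm, design = simulate_expression(config, truth)
    return SimResult(config, layout, genes, truth, libs, fpkm, design)


def emit_files(result: SimResult, out_dir: str | Path, write_genome: bool = False) -> dict[str, Path]:
    """Write every artifact as plain text readable by the pipeline readers.

    Emits per-library tag BEDs, the gene annotation TSV, the chromosome
    layout TSV, the expression and design TSVs, a GMT with the planted
    activated/repressed target sets, and the truth JSON. ``write_genome``
    additionally emits a random-base FASTA of the whole genome (large).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, lib in result.libraries.items():
        p = out / f"tags_{name}.bed"
        write_tags_bed(lib, p)
        paths[f"tags_{name}"] = p
    paths["genes"] = out / "genes.tsv"
    write_gene_annotation(result.genes, paths["genes"])
    paths["layout"] = out / "layout.tsv"
    result.layout.write_tsv(paths["layout"])
    paths["expression"] = out / "expression.tsv"
    result.fpkm.to_csv(paths["expression"], sep="\t")
    paths["design"] = out / "design.tsv"
    result.design.to_csv(paths["design"], sep="\t", index=False)
    paths["gene_sets"] = out / "planted_sets.gmt"
    sets = []
    for cls in ("activated_target", "repressed_target"):
        members = result.truth.genes_of_class(cls)
        if members:
            sets.append(GeneSet(f"planted_{cls}s", frozenset(members)))
    write_gmt(sets, paths["gene_sets"])
    paths["truth"] = out / "truth.json"
    result.truth.to_json(paths["truth"])
    if write_genome:
        rng = np.random.default_rng(result.config.seed + 4)
        paths["genome"] = out / "genome.fasta"
        with open(paths["genome"], "w") as fh:
            for chrom, length in result.layout.lengths.items():
                fh.write(f">{chrom}\n")
                seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
                for i in range(0, length, 80):
                    fh.write(seq[i:i + 80].tobytes().decode() + "\n")
    return paths
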