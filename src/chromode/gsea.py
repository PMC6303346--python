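"""Self-contained gene-set enrichment analysis.

Implements the weighted Kolmogorov-Smirnov-like running-sum statistic: for
a list of N genes ranked by a metric and a set of k members, the running
sum rises by |metric|^p / sum_set |metric|^p at each member ("hit") and
falls by 1/(N - k) at each non-member ("miss"); the enrichment score ES is
the signed maximal deviation from zero. Significance uses a gene-set
permutation null (members redrawn uniformly without replacement), which is
the appropriate scheme when too few phenotype labels exist to permute.
NES normalizes ES by the mean same-sign null magnitude, and the FDR q is
the standard NES-based ratio computed over all sets tested together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class RankedList:
    """Genes ordered by metric descending; ties lexicographic by gene_id."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        self.metric = np.asarray(self.metric, dtype=float)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    extremum_index: int
    leading_edge: list[str]


def rank_genes(
    table: ExpressionTable, contrast: str = "WT_vs_KO", eps: float = 0.01
) -> RankedList:
    """Rank by log2((mean WT FPKM + eps)/(mean KO FPKM + eps)), descending.

    Genes higher in WT than knockout rank at the top, so sets of
    WT-dependent genes score positive ES.
    """
    if contrast != "WT_vs_KO":
        raise ValueError(f"unknown contrast {contrast!r}")
    if table.fpkm.empty:
        raise ValueError("expression table is empty")
    wt = table.genotype_matrix("WT").mean(axis=1)
    ko = table.genotype_matrix("KO").mean(axis=1)
    metric = np.log2((wt + eps) / (ko + eps))
    frame = pd.DataFrame({"metric": metric}, index=table.fpkm.index)
    frame = frame.sort_index().sort_values("metric", ascending=False, kind="stable")
    return RankedList(list(frame.index), frame["metric"].to_numpy())


def _running_sum(
    metric: np.ndarray, hits: np.ndarray, weight_p: float
) -> np.ndarray:
    """Running sum for a boolean hit mask over a ranked metric vector."""
    w = np.abs(metric) ** weight_p
    hit_mass = w[hits].sum()
    n, k = metric.size, int(hits.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must hit the list but not exhaust it")
    step = np.where(hits, w / hit_mass if hit_mass > 0 else 0.0, -1.0 / (n - k))
    if hit_mass == 0:  # all member metrics exactly zero: fall back to equal weights
        step = np.where(hits, 1.0 / k, -1.0 / (n - k))
    return np.cumsum(step)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """(ES, running sum, extremum index): signed maximal deviation from 0."""
    hits = np.isin(ranked.genes, list(gene_set.members))
    if not hits.any():
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the ranked list")
    running = _running_sum(ranked.metric, hits, weight_p)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def permutation_null(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null ES sample: set members redrawn uniformly without replacement.

    Vectorized over permutations; deterministic given a seeded generator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    n = len(ranked)
    k = int(np.isin(ranked.genes, list(gene_set.members)).sum())
    if k == 0:
        raise ValueError("gene set has no gene in the ranked list")
    w = np.abs(ranked.metric) ** weight_p
    # hit positions per permutation: first k of a random argpartition
    keys = rng.random((n_perm, n))
    hit_idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    hit_mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit_mask, hit_idx, True, axis=1)
    hit_w = np.where(hit_mask, w, 0.0)
    hit_mass = hit_w.sum(axis=1, keepdims=True)
    safe_mass = np.where(hit_mass > 0, hit_mass, 1.0)
    step = np.where(hit_mask, hit_w / safe_mass, -1.0 / (n - k))
    degenerate = (hit_mass == 0).ravel()
    if degenerate.any():
        step[degenerate] = np.where(hit_mask[degenerate], 1.0 / k, -1.0 / (n - k))
    running = np.cumsum(step, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def nominal_p(observed_es: float, null_es: np.ndarray) -> float:
    """(k+1)/(n+1) fraction of same-sign null ES at least as extreme."""
    if observed_es >= 0:
        same = null_es[null_es >= 0]
        k = int((same >= observed_es).sum())
    else:
        same = null_es[null_es < 0]
        k = int((same <= observed_es).sum())
    return (k + 1) / (same.size + 1)


def normalize_es(es: float | np.ndarray, null_es: np.ndarray) -> float | np.ndarray:
    """NES = ES / mean(|same-sign null ES|)."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    pos_mean = pos.mean() if pos.size else np.nan
    neg_mean = np.abs(neg).mean() if neg.size else np.nan
    es_arr = np.asarray(es, dtype=float)
    out = np.where(es_arr >= 0, es_arr / pos_mean, es_arr / neg_mean)
    return float(out) if out.ndim == 0 else out


def normalize_and_fdr(
    observed: dict[str, float], nulls: dict[str, np.ndarray]
) -> pd.DataFrame:
    """NES, nominal p and NES-based FDR q for a family of sets.

    q(set) for a positive set = [fraction of all pooled null NES >= NES] /
    [fraction of observed NES >= NES], clipped to [0, 1]; mirrored for
    negative sets.
    """
    names = list(observed)
    nes_obs = np.array([normalize_es(observed[n], nulls[n]) for n in names])
    nes_null = np.concatenate([normalize_es(nulls[n], nulls[n]) for n in names])
    p_nom = np.array([nominal_p(observed[n], nulls[n]) for n in names])
    q = np.empty(len(names))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            null_frac = np.mean(nes_null >= nes) if nes_null.size else 0.0
            obs_frac = np.mean(nes_obs >= nes)
        else:
            null_frac = np.mean(nes_null <= nes) if nes_null.size else 0.0
            obs_frac = np.mean(nes_obs <= nes)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return pd.DataFrame(
        {"es": [observed[n] for n in names], "nes": nes_obs,
         "p_nominal": p_nom, "q_fdr": q},
        index=pd.Index(names, name="set"),
    )


def leading_edge(
    ranked: RankedList, gene_set: GeneSet, es: float, extremum_index: int
) -> list[str]:
    """Set members at ranks <= extremum for ES > 0, >= extremum for ES < 0."""
    members = gene_set.members
    if es >= 0:
        span = ranked.genes[: extremum_index + 1]
    else:
        span = ranked.genes[extremum_index:]
    return [g for g in span if g in members]


def run_gsea(
    ranked: RankedList,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> list[GseaResult]:
    """Full pipeline over a family of sets: ES, permutation null, NES/p/q,
    and leading-edge genes per set."""
    rng = np.random.default_rng(seed)
    observed: dict[str, float] = {}
    extremes: dict[str, int] = {}
    nulls: dict[str, np.ndarray] = {}
    for gs in gene_sets:
        es, _, idx = enrichment_score(ranked, gs, weight_p)
        observed[gs.name] = es
        extremes[gs.name] = idx
        nulls[gs.name] = permutation_null(ranked, gs, n_perm, weight_p, rng)
    stats = normalize_and_fdr(observed, nulls)
    results = []
    for gs in gene_sets:
        row = stats.loc[gs.name]
        results.append(
            GseaResult(
                gs.name, float(row["es"]), float(row["nes"]),
                float(row["p_nominal"]), float(row["q_fdr"]),
                extremes[gs.name],
                leading_edge(ranked, gs, float(row["es"]), extremes[gs.name]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with <3 fields: {line[:50]!r}")
        sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(gs.name + "\tchromode\t" + "\t".join(sorted(gs.members)) + "\n")


def read_rnk(path: str | Path) -> RankedList:
    """RNK: two columns, gene and metric; re-sorted descending on read."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"],
                        comment="#")
    frame = frame.set_index("gene").sort_index().sort_values(
        "metric", ascending=False, kind="stable")
    return RankedList(list(frame.index), frame["metric"].to_numpy())


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, m in zip(ranked.genes, ranked.metric):
            fh.write(f"{g}\t{m:.6g}\n")
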