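"""Co-occupancy grouping, feature annotation, summit-centered signal
matrices, and chromatin-mode classification of called peaks.

Two peak sets A and B (e.g. a chromatin factor and the transcription factor
recruiting it) are partitioned into A+B co-occupied, A-solo and B-solo
groups by >=1 bp overlap. Signal matrices are log2(RPKM + 1) values in
100-bp bins over summit +/- 5 kb; heatmap rows are ordered by repressive
mark level ascending with active-mark-descending tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeLayout, GenomicInterval, TagLibrary, overlap_join
from .islands import Island


class Group(str, Enum):
    A_AND_B = "A_and_B"
    A_SOLO = "A_solo"
    B_SOLO = "B_solo"


class FeatureClass(str, Enum):
    PROMOTER = "promoter"
    GENE_BODY = "gene_body"
    INTERGENIC = "intergenic"


class ChromatinMode(str, Enum):
    ME3 = "me3_marked"
    AC = "ac_marked"
    DUAL = "dual"
    UNMARKED = "unmarked"


@dataclass(frozen=True)
class PeakGroupAssignment:
    peak_id: str
    group: Group
    region: GenomicInterval
    alignment_center: int       # A summit for groups 1-2, B summit for group 3
    gene_ids: tuple[str, ...] = ()


def classify_cooccupancy(
    peaks_a: Sequence[Island], peaks_b: Sequence[Island]
) -> tuple[list[PeakGroupAssignment], float]:
    """Partition A peaks into A_and_B / A_solo and B peaks into B_solo.

    Overlap means >=1 shared bp with any peak of the other set; the second
    return value is the fraction of A peaks overlapping B. Each peak is
    counted once on its own side regardless of how many partners it hits.
    """
    if not peaks_a:
        raise ValueError("peak set A is empty")
    pairs = overlap_join([p.region for p in peaks_a], [p.region for p in peaks_b]) \
        if peaks_b else []
    a_hit = {i for i, _ in pairs}
    b_hit = {j for _, j in pairs}
    out: list[PeakGroupAssignment] = []
    for i, p in enumerate(peaks_a):
        group = Group.A_AND_B if i in a_hit else Group.A_SOLO
        out.append(PeakGroupAssignment(f"A_{i}", group, p.region, p.summit))
    for j, p in enumerate(peaks_b):
        if j not in b_hit:
            out.append(PeakGroupAssignment(f"B_{j}", Group.B_SOLO, p.region, p.summit))
    return out, len(a_hit) / len(peaks_a)


def restrict_to_tss(
    assignments: Sequence[PeakGroupAssignment],
    genes: Sequence[GeneModel],
    radius: int = 10_000,
) -> list[PeakGroupAssignment]:
    """Keep peaks whose alignment center lies within ``radius`` of any TSS.

    Association is many-to-many: each retained peak carries every gene whose
    TSS qualifies (sorted by gene_id).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept: list[PeakGroupAssignment] = []
    for a in assignments:
        hits = sorted(
            g.gene_id
            for g in by_chrom.get(a.region.chrom, [])
            if abs(a.alignment_center - g.tss) <= radius
        )
        if hits:
            kept.append(
                PeakGroupAssignment(a.peak_id, a.group, a.region,
                                    a.alignment_center, tuple(hits))
            )
    return kept


def annotate_feature(
    summit_chrom: str, summit: int, genes: Sequence[GeneModel]
) -> FeatureClass:
    """Promoter (TSS +/- 1 kb) > gene body (TSS + 1 kb strand-ward to TES) >
    intergenic, checked against every gene."""
    in_body = False
    for g in genes:
        if g.chrom != summit_chrom:
            continue
        if abs(summit - g.tss) <= 1000:
            return FeatureClass.PROMOTER
        if g.strand == "+":
            if g.tss + 1000 < summit <= g.tes:
                in_body = True
        else:
            if g.tes <= summit < g.tss - 1000:
                in_body = True
    return FeatureClass.GENE_BODY if in_body else FeatureClass.INTERGENIC


def feature_distribution(
    assignments: Sequence[PeakGroupAssignment], genes: Sequence[GeneModel]
) -> dict[str, float]:
    """Fraction of peaks per feature class (promoter / gene body / intergenic)."""
    counts = {f.value: 0 for f in FeatureClass}
    for a in assignments:
        counts[annotate_feature(a.region.chrom, a.alignment_center, genes).value] += 1
    n = max(1, len(assignments))
    return {k: v / n for k, v in counts.items()}


def build_signal_matrix(
    centers: Sequence[tuple[str, int]],
    lib: TagLibrary,
    layout: GenomeLayout | None = None,
    half_width: int = 5_000,
    bin_size: int = 100,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Signal matrix over center +/- half_width in ``bin_size`` bins.

    Values are log(RPKM + 1) with RPKM = count / (bin_kb * total_tags/1e6);
    the log base defaults to 2. Bins falling outside the chromosome read 0.
    Rows are labelled ``chrom:center``.
    """
    if lib.total_tags == 0:
        raise ValueError("tag library is empty")
    n_bins = (2 * half_width) // bin_size
    per_million = lib.total_tags / 1e6
    bin_kb = bin_size / 1000.0
    mat = np.zeros((len(centers), n_bins))
    for r, (chrom, center) in enumerate(centers):
        pos = lib.chrom_tags(chrom)
        lo = center - half_width
        edges = lo + np.arange(n_bins + 1) * bin_size
        counts = np.diff(np.searchsorted(pos, edges))
        if layout is not None and chrom in layout:
            starts = edges[:-1]
            counts[(starts < 0) | (edges[1:] > layout[chrom])] = 0
        else:
            counts[edges[:-1] < 0] = 0
        rpkm = counts / (bin_kb * per_million)
        mat[r] = np.log(rpkm + 1.0) / np.log(log_base)
    index = [f"{c}:{p}" for c, p in centers]
    return pd.DataFrame(mat, index=index)


def composite_profile(
    centers: Sequence[tuple[str, int]],
    lib: TagLibrary,
    layout: GenomeLayout | None = None,
    half_width: int = 5_000,
    bin_size: int = 100,
) -> np.ndarray:
    """Mean signal per bin across centers (column means of the matrix)."""
    if not centers:
        raise ValueError("need at least one center")
    return build_signal_matrix(centers, lib, layout, half_width, bin_size).to_numpy().mean(axis=0)


def order_rows(me3_matrix: pd.DataFrame, ac_matrix: pd.DataFrame) -> list[str]:
    """Heatmap row order: repressive-mark row mean ascending; ties (within
    1e-9) broken by active-mark row mean descending; stable thereafter."""
    if list(me3_matrix.index) != list(ac_matrix.index):
        raise ValueError("row ids of the two matrices differ")
    me3 = me3_matrix.to_numpy().mean(axis=1)
    ac = ac_matrix.to_numpy().mean(axis=1)
    me3_key = np.round(me3 / 1e-9).astype(np.int64)  # quantize: ties within 1e-9
    order = np.lexsort((np.arange(len(me3)), -ac, me3_key))
    return [me3_matrix.index[i] for i in order]


def classify_chromatin_mode(
    peak: Island | GenomicInterval,
    me3_islands: Sequence[Island],
    ac_islands: Sequence[Island],
) -> ChromatinMode:
    """Mode by >=1 bp overlap with called repressive/active mark islands."""
    region = peak.region if isinstance(peak, Island) else peak
    has_me3 = bool(overlap_join([region], [i.region for i in me3_islands])) \
        if me3_islands else False
    has_ac = bool(overlap_join([region], [i.region for i in ac_islands])) \
        if ac_islands else False
    if has_me3 and has_ac:
        return ChromatinMode.DUAL
    if has_me3:
        return ChromatinMode.ME3
    if has_ac:
        return ChromatinMode.AC
    return ChromatinMode.UNMARKED
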