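"""SICER-style enriched-region (island) detection with Poisson scoring.

The genome is tiled into fixed windows; windows whose tag count clears a
Poisson tail threshold against the genome-wide background density are
*eligible*, and eligible windows separated by at most ``gap`` ineligible
windows are linked into candidate islands. Each island is then tested
against a control-derived local expectation (floored at the background
rate), and islands are retained at a Benjamini-Hochberg FDR threshold.

Sharp transcription-factor peaks and broad histone-mark domains differ only
in the gap parameter (1 vs 3 windows by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomeLayout, GenomicInterval, TagLibrary

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IslandParams:
    """Calling parameters.

    window_w
        tiling window size in bp.
    gap_g
        maximal run of ineligible windows bridged inside one island;
        use 1 for sharp (TF) marks, 3 for broad domains.
    eligibility_p0
        Poisson tail probability below which a window's count is deemed
        eligible (SICER's window p-value convention).
    fdr_threshold
        Benjamini-Hochberg q cutoff for retaining islands.
    effective_genome_fraction
        fraction of the genome that is mappable; scales the background
        density.
    """

    window_w: int = 200
    gap_g: int = 1
    eligibility_p0: float = 0.2
    fdr_threshold: float = 1e-4
    effective_genome_fraction: float = 0.74

    def __post_init__(self) -> None:
        if self.window_w < 50:
            raise ValueError("window_w must be >= 50 bp")
        if self.gap_g < 0:
            raise ValueError("gap_g must be >= 0")
        if not 0 < self.eligibility_p0 < 1:
            raise ValueError("eligibility_p0 must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")


BROAD_PARAMS = IslandParams(gap_g=3)  # convention for H3K27me3-like domains


@dataclass(frozen=True)
class Island:
    """A called enriched region with its summit and statistics."""

    region: GenomicInterval
    score: float                # sum of -ln Poisson pmf over eligible windows (nats)
    treatment_tags: int
    control_tags: int
    p_value: float
    q_value: float
    summit: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not 0 <= self.q_value <= 1:
            raise ValueError("q_value must be in [0, 1]")
        if not self.region.start <= self.summit < self.region.end:
            raise ValueError("summit must lie within the island region")

    @property
    def chrom(self) -> str:
        return self.region.chrom


def bin_tags(lib: TagLibrary, layout: GenomeLayout, w: int) -> dict[str, np.ndarray]:
    """Per-window tag counts: ceil(L/w) windows per chromosome.

    Tags outside chromosome bounds are discarded; the sum of window counts
    equals the number of in-bounds tags.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, length in layout.lengths.items():
        n_win = -(-length // w)
        pos = lib.chrom_tags(chrom)
        pos = pos[(pos >= 0) & (pos < length)]
        counts[chrom] = np.bincount(pos // w, minlength=n_win).astype(np.int64)
    return counts


def eligibility_threshold(lambda_bg: float, p0: float) -> int:
    """Smallest integer c* with P(X >= c* | Poisson(lambda_bg)) < p0."""
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be > 0")
    c = max(1, int(stats.poisson.ppf(1 - p0, lambda_bg)))
    while stats.poisson.sf(c - 1, lambda_bg) >= p0:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lambda_bg) < p0:
        c -= 1
    return c


def link_islands(eligible_flags: np.ndarray, gap_g: int) -> list[tuple[int, int]]:
    """Maximal runs of eligible windows allowing gaps of <= gap_g windows.

    Returns half-open (start_window, end_window) pairs; islands begin and
    end on eligible windows.
    """
    flags = np.asarray(eligible_flags, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap_g + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def score_island(window_counts: Sequence[int] | np.ndarray, lambda_bg: float) -> float:
    """Aggregate island score: sum over eligible windows of -ln pmf(count; lambda)."""
    counts = np.asarray(window_counts)
    if counts.size == 0:
        return 0.0
    return float(-stats.poisson.logpmf(counts, lambda_bg).sum())


def call_islands(
    treatment: TagLibrary,
    control: TagLibrary,
    layout: GenomeLayout,
    params: IslandParams = IslandParams(),
) -> list[Island]:
    """Call enriched islands of treatment over control.

    The background rate is ``total_treatment_tags * w / (G * f_eff)`` tags
    per window. Per-island significance is a Poisson upper tail of the
    treatment tag count against the library-size-scaled control count in
    the island span, floored at the background expectation; q-values are
    Benjamini-Hochberg over all candidate islands genome-wide.
    """
    if treatment.total_tags == 0:
        raise ValueError("treatment library is empty")
    w = params.window_w
    effective_len = layout.total_length * params.effective_genome_fraction
    lambda_bg = treatment.total_tags * w / effective_len

    if control.total_tags == 0:
        log.warning("control library has zero tags; using background rate only")
        scale = 0.0
    else:
        scale = treatment.total_tags / control.total_tags

    c_star = eligibility_threshold(lambda_bg, params.eligibility_p0)
    t_counts = bin_tags(treatment, layout, w)
    c_counts = bin_tags(control, layout, w)

    candidates: list[tuple[GenomicInterval, float, int, int, float, int]] = []
    p_values: list[float] = []
    for chrom, length in layout.lengths.items():
        tc = t_counts[chrom]
        cc = c_counts[chrom]
        for ws, we in link_islands(tc >= c_star, params.gap_g):
            start_bp = ws * w
            end_bp = min(we * w, length)
            span = tc[ws:we]
            t_tags = int(span.sum())
            ctrl_tags = int(cc[ws:we].sum())
            expected = max(ctrl_tags * scale, lambda_bg * (we - ws))
            p = float(stats.poisson.sf(t_tags - 1, expected))
            score = score_island(span[span >= c_star], lambda_bg)
            max_win = ws + int(np.argmax(span))  # ties -> leftmost via argmax
            summit = min(max_win * w + w // 2, length - 1)
            region = GenomicInterval(chrom, start_bp, end_bp)
            candidates.append((region, score, t_tags, ctrl_tags, p, summit))
            p_values.append(p)

    if not candidates:
        return []
    q_values = multipletests(p_values, method="fdr_bh")[1]
    islands = [
        Island(region, score, t_tags, ctrl_tags, p, float(q), summit)
        for (region, score, t_tags, ctrl_tags, p, summit), q in zip(candidates, q_values)
        if q < params.fdr_threshold
    ]
    return islands


def extract_summit_sequences(
    islands: Sequence[Island],
    genome_fasta: str | Path,
    flank: int = 200,
) -> list[tuple[str, str]]:
    """Summit +/- flank sequences for motif discovery, as (id, sequence).

    Record ids are ``chrom:summit``; flanks are truncated at chromosome
    ends, so sequences are at most 2*flank + 1 bp.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    records: list[tuple[str, str]] = []
    for isl in islands:
        if isl.chrom not in genome:
            raise KeyError(f"chromosome {isl.chrom!r} absent from {genome_fasta}")
        chrom_len = len(genome[isl.chrom])
        lo = max(0, isl.summit - flank)
        hi = min(chrom_len, isl.summit + flank + 1)
        records.append((f"{isl.chrom}:{isl.summit}", str(genome[isl.chrom][lo:hi])))
    return records


def write_summit_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_islands_bed(islands: Sequence[Island], path: str | Path) -> None:
    """BED6+ with score, q-value and summit columns."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            fh.write(
                f"{isl.chrom}\t{isl.region.start}\t{isl.region.end}\t"
                f"island_{i}\t{isl.score:.3f}\t.\t{isl.q_value:.3e}\t{isl.summit}\n"
            )


def read_islands_bed(path: str | Path) -> list[Island]:
    islands = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        c, s, e, _name, score, _strand, q, summit = line.split("\t")
        islands.append(
            Island(
                GenomicInterval(c, int(s), int(e)),
                float(score), 0, 0, float(q), float(q), int(summit),
            )
        )
    return islands
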