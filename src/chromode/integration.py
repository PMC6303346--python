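"""Cross-referencing of chromatin-mode-classified peaks with differential
expression and enrichment results: the mode-of-action report.

The central question this module operationalizes: do factor-bound,
active-mark (H3K27ac) peaks sit at genes that *lose* expression when the
factor is knocked out (direct activation), while repressive-mark
(H3K27me3) peaks sit at genes that *gain* expression (classical
repression)? "Up"/"down" are knockout-relative throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .cooccupancy import ChromatinMode, classify_chromatin_mode
from .core import GeneModel, TagLibrary
from .expression import ExpressionTable
from .islands import Island


def genes_with_peaks_near_tss(
    gene_list: Sequence[str],
    peaks: Sequence[Island],
    genes: Sequence[GeneModel],
    radius: int = 10_000,
) -> tuple[list[str], list[Island]]:
    """Genes from ``gene_list`` with >=1 peak summit within ``radius`` of
    their TSS, plus the deduplicated peaks involved.

    One gene may carry several peaks and one peak may serve several genes,
    so the peak count can exceed the gene count. Genes absent from the
    annotation are skipped with a warning.
    """
    import warnings

    by_id = {g.gene_id: g for g in genes}
    qualifying: list[str] = []
    peak_ids: set[int] = set()
    for gid in gene_list:
        g = by_id.get(gid)
        if g is None:
            warnings.warn(f"gene {gid!r} absent from annotation; skipped")
            continue
        hit = False
        for i, p in enumerate(peaks):
            if p.chrom == g.chrom and abs(p.summit - g.tss) <= radius:
                hit = True
                peak_ids.add(i)
        if hit:
            qualifying.append(gid)
    return qualifying, [peaks[i] for i in sorted(peak_ids)]


def unique_target_genes(
    peaks: Sequence[Island],
    genes: Sequence[GeneModel],
    radius: int = 10_000,
) -> set[str]:
    """Union over peaks of all genes with a TSS within ``radius`` of the summit."""
    out: set[str] = set()
    for p in peaks:
        for g in genes:
            if g.chrom == p.chrom and abs(p.summit - g.tss) <= radius:
                out.add(g.gene_id)
    return out


@dataclass
class ModeOfActionReport:
    """Per-gene cross-reference of peaks, chromatin mode and DE calls.

    ``per_gene`` columns: gene_id (index), de_call, leading_edge (bool),
    n_peaks, modes (comma-joined ChromatinMode values of peaks within the
    TSS radius). ``summary`` holds counts recomputable from per_gene.
    """

    per_gene: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        pg = self.per_gene
        mode_counts: dict[str, int] = {m.value: 0 for m in ChromatinMode}
        for modes in pg["modes"]:
            for m in filter(None, modes.split(",")):
                mode_counts[m] += 1
        return {
            "n_genes": int(len(pg)),
            "n_genes_with_peaks": int((pg["n_peaks"] > 0).sum()),
            "n_peaks_total": int(pg["n_peaks"].sum()),
            "peak_mode_counts": mode_counts,
            "de_call_counts": pg["de_call"].value_counts().to_dict(),
        }


def build_report(
    genes: Sequence[GeneModel],
    peaks: Sequence[Island],
    me3_islands: Sequence[Island],
    ac_islands: Sequence[Island],
    de_table: pd.DataFrame,
    leading_edge_genes: Sequence[str] = (),
    radius: int = 10_000,
) -> ModeOfActionReport:
    """Assemble the per-gene mode-of-action table.

    For every gene: its DE call, leading-edge membership, and the chromatin
    modes of all peaks whose summit falls within ``radius`` of its TSS.
    """
    peak_modes = [classify_chromatin_mode(p, me3_islands, ac_islands) for p in peaks]
    le = set(leading_edge_genes)
    rows = []
    for g in genes:
        near = [
            i for i, p in enumerate(peaks)
            if p.chrom == g.chrom and abs(p.summit - g.tss) <= radius
        ]
        call = (
            de_table.loc[g.gene_id, "call"]
            if g.gene_id in de_table.index else "unchanged"
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "de_call": call,
                "leading_edge": g.gene_id in le,
                "n_peaks": len(near),
                "modes": ",".join(peak_modes[i].value for i in near),
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene_id")
    report = ModeOfActionReport(per_gene)
    report.summary = report.recompute_summary()
    return report


def mode_by_de_contingency(report: ModeOfActionReport) -> dict:
    """2x2 table of (active-mark, down) vs (repressive-mark, up) gene counts
    with a Haldane-corrected odds ratio.

    A gene counts as ac-marked (me3-marked) when any of its TSS-proximal
    peaks carries that mode. The odds ratio contrasts "ac-marked and down
    in KO" against "me3-marked and up in KO"; Haldane's 0.5 is added to
    every cell when any cell is zero. Returns the table plus the OR, or an
    ``"undefined"`` sentinel for an all-zero table.
    """
    pg = report.per_gene
    has_ac = pg["modes"].str.contains(ChromatinMode.AC.value).fillna(False)
    has_me3 = pg["modes"].str.contains(ChromatinMode.ME3.value).fillna(False)
    down = pg["de_call"] == "down"
    up = pg["de_call"] == "up"
    table = np.array(
        [
            [int((has_ac & down).sum()), int((has_ac & up).sum())],
            [int((has_me3 & down).sum()), int((has_me3 & up).sum())],
        ],
        dtype=float,
    )
    if table.sum() == 0:
        return {"table": table.astype(int).tolist(), "odds_ratio": "undefined"}
    t = table + 0.5 if (table == 0).any() else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"table": table.astype(int).tolist(), "odds_ratio": float(odds)}


def mark_expression_correlation(
    mark_lib: TagLibrary,
    genes: Sequence[GeneModel],
    expr: ExpressionTable,
    window: int = 1_000,
) -> float:
    """Spearman rho between promoter-window mark RPKM and mean FPKM.

    The promoter window is TSS +/- ``window``. Returns NaN (undefined) when
    either variable is constant across genes.
    """
    shared = [g for g in genes if g.gene_id in expr.fpkm.index]
    if len(shared) < 10:
        raise ValueError("need >=10 genes present in the expression table")
    per_million = mark_lib.total_tags / 1e6
    width_kb = 2 * window / 1000.0
    rpkm = np.array(
        [
            mark_lib.count_in(g.chrom, max(0, g.tss - window), g.tss + window)
            / (width_kb * per_million)
            for g in shared
        ]
    )
    fpkm = expr.fpkm.loc[[g.gene_id for g in shared]].mean(axis=1).to_numpy()
    if np.all(rpkm == rpkm[0]) or np.all(fpkm == fpkm[0]):
        return float("nan")
    rho, _ = sp_stats.spearmanr(rpkm, fpkm)
    return float(rho)
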