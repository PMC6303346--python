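"""FPKM computation and differential-expression filtering.

DE calling applies the fold-change / FDR / minimum-expression rules of the
study design: a gene is "up" when KO/WT >= fc_threshold with q < fdr and
mean KO FPKM >= min_fpkm, "down" for the mirror-image rule, and "band_1p5"
when the fold change lands in [1.5, 2) with q < fdr. Significance comes
from a two-sample t statistic on log2(FPKM + 1) across replicates; with
two replicates per genotype the per-gene variance is hopeless on its own,
so by default each genotype's variance is shrunk toward the grand mean
variance across genes (moderated test; prior df configurable). A plain
Welch test is available for larger designs, and externally computed
p-values may be supplied and passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionTable:
    """Gene x sample FPKM matrix with genotype/replicate metadata.

    ``fpkm`` is indexed by gene_id; ``design`` maps each column of ``fpkm``
    to a genotype in {WT, KO} and a replicate index.
    """

    fpkm: pd.DataFrame
    design: pd.DataFrame  # columns: sample, genotype, replicate

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be >= 0")
        missing = set(self.design["sample"]) - set(self.fpkm.columns)
        if missing:
            raise ValueError(f"design samples absent from table: {sorted(missing)}")

    def samples(self, genotype: str) -> list[str]:
        sel = self.design.loc[self.design["genotype"] == genotype, "sample"]
        return list(sel)

    def genotype_matrix(self, genotype: str) -> np.ndarray:
        return self.fpkm[self.samples(genotype)].to_numpy(dtype=float)


def compute_fpkm(
    fragment_counts: np.ndarray | Sequence[float] | float,
    gene_length_bp: np.ndarray | Sequence[float] | float,
    total_mapped_fragments: float,
) -> np.ndarray | float:
    """FPKM = count / (length_kb * total/1e6)."""
    length = np.asarray(gene_length_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be > 0")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be > 0")
    counts = np.asarray(fragment_counts, dtype=float)
    out = counts / ((length / 1000.0) * (total_mapped_fragments / 1e6))
    return float(out) if out.ndim == 0 else out


def _moderated_welch(
    wt: np.ndarray, ko: np.ndarray, prior_df: float
) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and p-value on log2(FPKM+1), variances shrunk toward the
    grand mean variance with ``prior_df`` pseudo-genes (prior_df=0 recovers
    plain Welch with Satterthwaite df)."""
    lw, lk = np.log2(wt + 1.0), np.log2(ko + 1.0)
    n1, n2 = lw.shape[1], lk.shape[1]
    m1, m2 = lw.mean(axis=1), lk.mean(axis=1)
    v1, v2 = lw.var(axis=1, ddof=1), lk.var(axis=1, ddof=1)
    if prior_df > 0:
        s0 = float(np.mean(np.concatenate([v1, v2])))
        v1 = (v1 + prior_df * s0) / (1.0 + prior_df)
        v2 = (v2 + prior_df * s0) / (1.0 + prior_df)
        df = np.full(v1.shape, (n1 - 1 + n2 - 1) * (1.0 + prior_df))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (v1 / n1 + v2 / n2) ** 2
            den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            df = np.where(den > 0, num / den, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(v1 / n1 + v2 / n2)
        t = np.where(se > 0, (m2 - m1) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, 0.0, 1.0)


def call_de(
    table: ExpressionTable,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
    min_fpkm: float = 1.0,
    prior_df: float = 10.0,
    p_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential-expression table with the study's filtering rules.

    Returns a DataFrame indexed by gene_id with columns mean_fpkm_wt,
    mean_fpkm_ko, log2_fold_change (KO over WT), p_value, q_value, call.
    Calls: up (KO/WT >= fc, q < fdr, mean KO FPKM >= min_fpkm), down
    (mirror), band_1p5 (1.5 <= fold < fc, q < fdr), else unchanged. Fold
    changes are ratios of mean FPKM with no pseudocount; the min-FPKM gate
    handles near-zero expression. ``p_values`` overrides the built-in test
    (e.g. when an external DE model supplies them).
    """
    for genotype in ("WT", "KO"):
        if len(table.samples(genotype)) < 2:
            raise ValueError(f"need >=2 replicates for genotype {genotype}")
    wt = table.genotype_matrix("WT")
    ko = table.genotype_matrix("KO")
    mean_wt = wt.mean(axis=1)
    mean_ko = ko.mean(axis=1)

    if p_values is not None:
        p = p_values.reindex(table.fpkm.index).to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ValueError("supplied p-values missing for some genes")
    else:
        _, p = _moderated_welch(wt, ko, prior_df)
    q = multipletests(p, method="fdr_bh")[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_up = np.where(mean_wt > 0, mean_ko / mean_wt, np.inf)
        ratio_down = np.where(mean_ko > 0, mean_wt / mean_ko, np.inf)
        ratio_up[(mean_ko == 0) & (mean_wt == 0)] = 1.0
        ratio_down[(mean_ko == 0) & (mean_wt == 0)] = 1.0
        lfc = np.log2(ratio_up)

    sig = q < fdr
    up = sig & (ratio_up >= fc_threshold) & (mean_ko >= min_fpkm)
    down = sig & (ratio_down >= fc_threshold) & (mean_wt >= min_fpkm)
    fold = np.maximum(ratio_up, ratio_down)
    band = sig & ~up & ~down & (fold >= 1.5) & (fold < fc_threshold)
    call = np.where(up, "up", np.where(down, "down",
                    np.where(band, "band_1p5", "unchanged")))
    return pd.DataFrame(
        {
            "mean_fpkm_wt": mean_wt,
            "mean_fpkm_ko": mean_ko,
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=table.fpkm.index,
    )


def read_expression_tsv(expr_path: str, design_path: str) -> ExpressionTable:
    """Read a gene x sample FPKM TSV (first column gene_id) and a design TSV
    with columns sample, genotype, replicate."""
    fpkm = pd.read_csv(expr_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    return ExpressionTable(fpkm, design)
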