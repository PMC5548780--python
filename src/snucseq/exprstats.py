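"""Expression gating, core-gene discovery, penetrance and CoV statistics.

A gene is "expressed" when its FPKM reaches 4 in at least 5 samples — the
gate applied throughout the analysis.  Core genes are those expressed at
FPKM >= 4 AND ranked within the top 500 by FPKM in *every* nucleus of a
reference group: constitutive, high-abundance identity markers with a low
coefficient of variation.  Penetrance is the percentage of samples
expressing a gene, which rises with mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "gate_expressed",
    "rank_genes_per_sample",
    "core_genes",
    "gene_summaries",
    "penetrance_expression_correlation",
]

FPKM_MIN_DEFAULT = 4.0
MIN_SAMPLES_DEFAULT = 5
TOP_RANK_DEFAULT = 500


def gate_expressed(
    matrix: ExpressionMatrix,
    fpkm_min: float = FPKM_MIN_DEFAULT,
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> tuple[set[str], pd.Series]:
    """Genes with FPKM >= ``fpkm_min`` in at least ``min_samples`` samples.

    Returns the expressed-gene set and the per-gene qualifying-sample count.
    Boundaries are inclusive on both thresholds.
    """
    if fpkm_min <= 0 or min_samples <= 0:
        raise ValueError("fpkm_min and min_samples must be positive")
    if min_samples > matrix.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({matrix.n_samples})")
    qualifying = (matrix.fpkm >= fpkm_min).sum(axis=1)
    expressed = set(qualifying.index[qualifying >= min_samples])
    return expressed, qualifying


def rank_genes_per_sample(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Descending-FPKM rank of every gene within each sample.

    The highest-FPKM gene has rank 1; ties receive the minimum (competition)
    rank, so "top 500" is conservative under ties.
    """
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty matrix")
    return matrix.fpkm.rank(axis=0, method="min", ascending=False).astype(int)


def core_genes(
    matrix: ExpressionMatrix,
    group_samples: list[str],
    top_rank: int = TOP_RANK_DEFAULT,
    fpkm_min: float = FPKM_MIN_DEFAULT,
) -> set[str]:
    """Genes at FPKM >= ``fpkm_min`` with rank <= ``top_rank`` in every
    sample of ``group_samples``."""
    if not group_samples:
        raise ValueError("group_samples is empty")
    sub = matrix.subset_samples(group_samples)
    ranks = rank_genes_per_sample(sub)
    ok = ((sub.fpkm >= fpkm_min) & (ranks <= top_rank)).all(axis=1)
    return set(ok.index[ok])


def gene_summaries(
    matrix: ExpressionMatrix,
    fpkm_min: float = FPKM_MIN_DEFAULT,
    min_samples: int = MIN_SAMPLES_DEFAULT,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-gene mean, SD, CoV, penetrance, expressed flag, best/worst rank.

    CoV = SD / mean (population SD by default, ``ddof=0``); undefined (NaN,
    flagged in ``cov_defined``) where the mean is 0.  Penetrance is the
    percentage of samples with FPKM >= ``fpkm_min``.
    """
    fpkm = matrix.fpkm
    mean = fpkm.mean(axis=1)
    sd = fpkm.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sd / mean
    cov[mean == 0] = np.nan
    penetrance = 100.0 * (fpkm >= fpkm_min).sum(axis=1) / matrix.n_samples
    expressed, qualifying = gate_expressed(matrix, fpkm_min, min_samples)
    ranks = rank_genes_per_sample(matrix)
    return pd.DataFrame({
        "mean_fpkm": mean,
        "sd_fpkm": sd,
        "cov": cov,
        "cov_defined": mean > 0,
        "penetrance": penetrance,
        "n_qualifying": qualifying,
        "expressed": fpkm.index.isin(list(expressed)),
        "best_rank": ranks.min(axis=1),
        "worst_rank": ranks.max(axis=1),
    })


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    defined: bool


def penetrance_expression_correlation(summary: pd.DataFrame) -> SpearmanResult:
    """Spearman correlation between per-gene mean FPKM and penetrance."""
    if len(summary) < 3:
        raise ValueError("need at least 3 genes")
    x = summary["mean_fpkm"].to_numpy()
    y = summary["penetrance"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, False)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), True)
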