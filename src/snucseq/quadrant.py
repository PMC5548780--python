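"""Quadrant co-expression analysis and negative-binomial exact testing.

Each nucleus is summarized by the mean FPKM of two marker panels (x and y)
and classified by an FPKM threshold of 4 on each axis: Q1 (y high only),
Q2 (both high), Q3 (both low), Q4 (x high only).  A condition shift into a
focal quadrant (typically Q2, the co-expressing state) is tested with a
two-sided Fisher exact test on the condition x membership 2x2 table.
Between-quadrant differential expression uses a DESeq-style exact test:
median-of-ratios size factors, method-of-moments pooled dispersion, and a
conditional NB test on each gene's count total, with Benjamini-Hochberg
adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetPanel

__all__ = [
    "QuadrantResult",
    "DEResult",
    "quadrant_assign",
    "fisher_exact_2x2",
    "quadrant_shift_test",
    "quadrant_chi2_test",
    "size_factors",
    "estimate_dispersion",
    "nb_exact_de",
    "bh_adjust",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class QuadrantResult:
    """Per-sample panel summaries and quadrant calls."""

    table: pd.DataFrame          # sample, x_summary, y_summary, quadrant
    panel_x: str
    panel_y: str
    threshold: float

    def occupancy(self, conditions: pd.Series) -> pd.DataFrame:
        """Counts and fractions per condition x quadrant."""
        t = self.table.copy()
        t["condition"] = conditions.loc[t.index].to_numpy()
        counts = (t.groupby(["condition", "quadrant"], observed=False)
                  .size().unstack(fill_value=0))
        for q in QUADRANTS:
            if q not in counts.columns:
                counts[q] = 0
        counts = counts[list(QUADRANTS)]
        fractions = counts.div(counts.sum(axis=1), axis=0)
        out = counts.join(fractions, lsuffix="_n", rsuffix="_frac")
        return out


def quadrant_assign(
    matrix: ExpressionMatrix,
    panel_x: GeneSetPanel,
    panel_y: GeneSetPanel,
    threshold: float = 4.0,
    summarizer: str = "mean",
) -> QuadrantResult:
    """Classify every sample into Q1-Q4 by thresholded panel summaries.

    ``summarizer`` is the per-sample aggregate of FPKM over panel members:
    "mean" (default), "median" or "max".  An axis value exactly at the
    threshold counts as high (consistent with the FPKM >= 4 gate).
    """
    for p in (panel_x, panel_y):
        missing = [g for g in p.members if g not in matrix.fpkm.index]
        if missing:
            raise KeyError(f"panel {p.name!r} genes absent from matrix: {missing}")
    agg = {"mean": np.mean, "median": np.median, "max": np.max}.get(summarizer)
    if agg is None:
        raise ValueError(f"unknown summarizer {summarizer!r}")
    xs = matrix.fpkm.loc[list(panel_x.members)].apply(agg, axis=0)
    ys = matrix.fpkm.loc[list(panel_y.members)].apply(agg, axis=0)
    x_high = xs >= threshold
    y_high = ys >= threshold
    quad = np.where(x_high & y_high, "Q2",
                    np.where(~x_high & y_high, "Q1",
                             np.where(x_high & ~y_high, "Q4", "Q3")))
    table = pd.DataFrame({"x_summary": xs, "y_summary": ys, "quadrant": quad},
                         index=matrix.sample_ids)
    return QuadrantResult(table=table, panel_x=panel_x.name, panel_y=panel_y.name,
                          threshold=threshold)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Conditions on both margins; the p-value sums hypergeometric
    probabilities not exceeding the observed table's probability (with a
    1e-7 relative slack).  A zero margin makes every table in the support
    identical, giving p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return 1.0 if p > 1.0 - 1e-12 else p


def quadrant_shift_test(
    result: QuadrantResult,
    conditions: pd.Series,
    focal_quadrant: str = "Q2",
) -> tuple[pd.DataFrame, float]:
    """Fisher test of condition x (in focal quadrant vs not).

    Returns the 2x2 contingency table (conditions as rows) and the
    two-sided p.
    """
    if focal_quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {focal_quadrant!r}")
    conds = conditions.loc[result.table.index]
    levels = sorted(set(conds))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    in_focal = result.table["quadrant"] == focal_quadrant
    rows = []
    for lv in levels:
        sel = conds == lv
        rows.append([int((in_focal & sel).sum()), int((~in_focal & sel).sum())])
    table = pd.DataFrame(rows, index=levels, columns=[focal_quadrant, "other"])
    return table, fisher_exact_2x2(table.to_numpy())


def quadrant_chi2_test(result: QuadrantResult, conditions: pd.Series) -> tuple[pd.DataFrame, float]:
    """Alternative 2x4 chi-square test over full quadrant occupancy."""
    conds = conditions.loc[result.table.index]
    levels = sorted(set(conds))
    counts = pd.DataFrame(0, index=levels, columns=list(QUADRANTS))
    for lv in levels:
        vc = result.table.loc[(conds == lv).to_numpy(), "quadrant"].value_counts()
        for q, n in vc.items():
            counts.loc[lv, q] = int(n)
    used = counts.loc[:, counts.sum(axis=0) > 0]
    _chi2, p, _dof, _exp = stats.chi2_contingency(used.to_numpy())
    return counts, float(p)


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DEResult:
    """Per-gene DESeq-style exact-test results."""

    table: pd.DataFrame   # mean_a, mean_b, dispersion, log2_fold_change, pvalue, qvalue
    size_factors: pd.Series


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (ratio to the gene geometric mean)."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts.to_numpy().astype(float))
    finite_rows = np.isfinite(log_counts).all(axis=1)
    if finite_rows.sum() == 0:
        raise ValueError("no gene has nonzero counts in every sample")
    log_geo = log_counts[finite_rows].mean(axis=1, keepdims=True)
    ratios = log_counts[finite_rows] - log_geo
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(norm_a: np.ndarray, norm_b: np.ndarray,
                        floor: float = 1e-8) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled across groups.

    For each group, d = (var - mean) / mean^2 on normalized counts; the
    pooled estimate is the sample-size-weighted average, floored.
    """
    def mom(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (v - m) / m ** 2
        return np.where(np.isfinite(d), d, 0.0)

    na, nb = norm_a.shape[1], norm_b.shape[1]
    pooled = (na * mom(norm_a) + nb * mom(norm_b)) / (na + nb)
    return np.maximum(pooled, floor)


def _nb_total_params(q: float, disp: float, sf: np.ndarray) -> tuple[float, float]:
    """Moment-matched NB(mean, size) for a sum of per-sample NB counts.

    Per-sample mean is q * s_j with variance q s_j + disp (q s_j)^2; the
    group total is matched by mean and variance.
    """
    mu = q * sf.sum()
    var = mu + disp * (q ** 2) * (sf ** 2).sum()
    if var <= mu:  # Poisson limit
        return mu, np.inf
    size = mu ** 2 / (var - mu)
    return mu, size


def _nb_pmf(x: np.ndarray, mu: float, size: float) -> np.ndarray:
    if np.isinf(size):
        return stats.poisson.pmf(x, mu)
    p = size / (size + mu)
    return stats.nbinom.pmf(x, size, p)


def nb_exact_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    dispersion_floor: float = 1e-8,
    sf: pd.Series | None = None,
) -> DEResult:
    """Two-group NB exact test per gene, conditioning on the count total.

    For each gene with observed group sums (k_a, k_b), every split (a, b)
    of k_a + k_b is scored by P(A = a) P(B = b) under moment-matched NB
    group-total distributions; the two-sided p is the probability mass of
    splits no more likely than the observed one, normalized over the
    support.  In the dispersion -> 0, equal-size-factor limit this is the
    binomial exact test of k_a given the total.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    for df in (counts_a, counts_b):
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
    genes = list(counts_a.index)
    if list(counts_b.index) != genes:
        raise ValueError("count frames must share the same gene index")
    if sf is None:
        joint = pd.concat([counts_a, counts_b], axis=1)
        sf = size_factors(joint)
    missing = [c for c in list(counts_a.columns) + list(counts_b.columns)
               if c not in sf.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing}")
    sf_a = sf[counts_a.columns].to_numpy()
    sf_b = sf[counts_b.columns].to_numpy()
    norm_a = counts_a.to_numpy() / sf_a[None, :]
    norm_b = counts_b.to_numpy() / sf_b[None, :]
    disp = estimate_dispersion(norm_a, norm_b, floor=dispersion_floor)

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_b / mean_a)

    ka = counts_a.to_numpy().sum(axis=1)
    kb = counts_b.to_numpy().sum(axis=1)
    pvals = np.ones(len(genes))
    for i in range(len(genes)):
        total = int(ka[i] + kb[i])
        if total == 0:
            continue
        # common-mean estimate under the null, per normalized unit
        q = (ka[i] + kb[i]) / (sf_a.sum() + sf_b.sum())
        mu_a, size_a = _nb_total_params(q, disp[i], sf_a)
        mu_b, size_b = _nb_total_params(q, disp[i], sf_b)
        # the conditional support is 0..total, but mass beyond ~12 sd of
        # either group total is far below any attainable p-value; windowing
        # keeps the enumeration linear in the sd, not the total
        sd_a = np.sqrt(mu_a + (mu_a ** 2 / size_a if np.isfinite(size_a) else 0.0))
        lo = int(max(0, min(mu_a - 12 * sd_a, ka[i] - 1)))
        hi = int(min(total, max(mu_a + 12 * sd_a, ka[i] + 1)))
        a_support = np.arange(lo, hi + 1)
        pa = _nb_pmf(a_support, mu_a, size_a)
        pb = _nb_pmf(total - a_support, mu_b, size_b)
        probs = pa * pb
        denom = probs.sum()
        if denom <= 0:
            continue
        p_obs = probs[int(ka[i]) - lo]
        pvals[i] = min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum() / denom)
    qvals = bh_adjust(pvals)
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "dispersion": disp,
        "log2_fold_change": lfc, "pvalue": pvals, "qvalue": qvals,
    }, index=genes)
    return DEResult(table=table, size_factors=sf)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    _rej, q, _a, _b = multipletests(p, method="fdr_bh")
    return q
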