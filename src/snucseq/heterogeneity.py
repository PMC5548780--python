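"""Pairwise-correlation structure, subgroup discovery and PCA embedding.

Sample-to-sample Pearson correlation is computed on log2(FPKM + 1) values
over gated genes.  Subgroups are flat clusters of the average-linkage tree
on distance 1 - r, cut at height 0.75; with four well-separated nuclear
states this yields the Sham A/B and TAC A/B branches.  The correlation
densities of the two conditions are compared with a two-sided
Mann-Whitney U test (exact enumeration at small n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

__all__ = [
    "pairwise_correlation",
    "offdiagonal_values",
    "correlation_density_test",
    "cluster_subgroups",
    "pca_embedding",
    "SubgroupResult",
]


def pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pearson correlation between sample columns of log2(FPKM+1).

    Zero-variance samples are excluded with a warning flag (dropped from the
    result).  Restrict to gated genes by passing ``genes``.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    data = matrix.fpkm if genes is None else matrix.fpkm.loc[genes]
    x = np.log2(data.to_numpy() + 1.0) if log_transform else data.to_numpy().astype(float)
    sds = x.std(axis=0)
    keep = sds > 0
    if not keep.all():
        import warnings

        dropped = [s for s, k in zip(data.columns, keep) if not k]
        warnings.warn(f"excluding zero-variance sample(s): {dropped}")
    cols = [s for s, k in zip(data.columns, keep) if k]
    r = np.corrcoef(x[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=cols, columns=cols)


def offdiagonal_values(corr: pd.DataFrame, samples: list[str] | None = None) -> np.ndarray:
    """Upper-triangle off-diagonal correlations, optionally within a sample set."""
    if samples is not None:
        corr = corr.loc[samples, samples]
    m = corr.to_numpy()
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def _mwu_exact_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration of all group assignments.

    Handles ties via midranks.  Two-sided p = 2 x smaller tail probability,
    capped at 1.
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    us = []
    idx = np.arange(n + m)
    for comb in combinations(idx, n):
        r = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        us.append(r)
    us = np.asarray(us)
    eps = 1e-9
    p_low = np.mean(us <= u_obs + eps)
    p_high = np.mean(us >= u_obs - eps)
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def correlation_density_test(
    corrs_a: np.ndarray,
    corrs_b: np.ndarray,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two sets of correlation values.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    values; otherwise the normal approximation with tie and continuity
    correction.  Returns (U statistic of the first group, two-sided p).
    """
    a = np.asarray(corrs_a, dtype=float)
    b = np.asarray(corrs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        return _mwu_exact_two_sided(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SubgroupResult:
    """Subgroup labels, the linkage tree behind them, and the PC embedding."""

    linkage: np.ndarray | None
    cut_height: float | None
    labels: pd.Series                       # sample -> subgroup label
    correlation: pd.DataFrame | None
    pc_coords: pd.DataFrame | None = None   # samples x PC1..PC3
    explained_variance: np.ndarray | None = None


def cluster_subgroups(
    corr: pd.DataFrame,
    cut_height: float = 0.75,
    conditions: pd.Series | None = None,
) -> SubgroupResult:
    """Average-linkage clustering of samples on distance 1 - r, cut flat.

    Labels are named ``<majority condition> <letter>`` when per-sample
    conditions are given, else ``S<k>``.
    """
    samples = list(corr.index)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = average(squareform(d, checks=False))
    flat = fcluster(z, t=cut_height, criterion="distance")
    labels = {}
    # stable label order: clusters in order of first appearance
    order: dict[int, int] = {}
    for c in flat:
        order.setdefault(c, len(order))
    if conditions is not None:
        per_cluster: dict[int, list[str]] = {}
        for s, c in zip(samples, flat):
            per_cluster.setdefault(c, []).append(s)
        counters: dict[str, int] = {}
        names: dict[int, str] = {}
        for c in sorted(per_cluster, key=lambda c: order[c]):
            conds = [conditions[s] for s in per_cluster[c]]
            majority = max(set(conds), key=conds.count)
            counters[majority] = counters.get(majority, 0)
            names[c] = f"{majority} {chr(ord('A') + counters[majority])}"
            counters[majority] += 1
        labels = {s: names[c] for s, c in zip(samples, flat)}
    else:
        labels = {s: f"S{order[c] + 1}" for s, c in zip(samples, flat)}
    return SubgroupResult(
        linkage=z, cut_height=cut_height,
        labels=pd.Series(labels, name="subgroup").loc[samples],
        correlation=corr)


def pca_embedding(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    n_components: int = 3,
) -> SubgroupResult:
    """PCA over samples after gene-wise standardization of FPKM.

    Each gene is transformed to zero mean, unit variance across samples;
    constant genes are dropped.  PC signs are oriented so the loading of
    largest magnitude is positive.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    data = matrix.fpkm if genes is None else matrix.fpkm.loc[genes]
    x = data.to_numpy().astype(float)
    sds = x.std(axis=1)
    x = x[sds > 0]
    if x.shape[0] < 3:
        raise ValueError("fewer than 3 non-constant genes")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    n_comp = min(n_components, matrix.n_samples - 1, z.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(z.T)  # samples x components
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    pc_cols = [f"PC{j + 1}" for j in range(n_comp)]
    return SubgroupResult(
        linkage=None, cut_height=None,
        labels=pd.Series(index=data.columns, dtype=object, name="subgroup"),
        correlation=None,
        pc_coords=pd.DataFrame(coords, index=data.columns, columns=pc_cols),
        explained_variance=pca.explained_variance_ratio_,
    )
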