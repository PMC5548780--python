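"""In-silico pooling, detection-saturation and correlation-saturation.

Read subsampling is modelled at the gene-count level: drawing ``n_reads``
counts without replacement from a sample's count vector (multivariate
hypergeometric), a surrogate for subsampling aligned reads.  Pooling sums
the counts of all member nuclei of a condition and subsamples pools at a
fixed depth, which averages out single-nucleus bimodality — the masking
that hides subgroup-confined signal from pooled and bulk assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable

__all__ = [
    "subsample_counts",
    "recompute_fpkm",
    "in_silico_pool",
    "detection_saturation",
    "correlation_saturation",
    "SaturationCurve",
]


@dataclass
class SaturationCurve:
    """Replicated detection counts or correlations along a depth/size axis."""

    x: np.ndarray                # depth (reads) or set size (samples)
    values: list[np.ndarray]     # replicate values per x
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if not (np.diff(self.x) > 0).all():
            raise ValueError("x must be strictly increasing")
        if any(len(v) < 1 for v in self.values):
            raise ValueError("each x needs at least one replicate")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x,
            "mean": [float(np.mean(v)) for v in self.values],
            "sd": [float(np.std(v, ddof=0)) for v in self.values],
            "reps": [len(v) for v in self.values],
        })


def subsample_counts(
    counts: np.ndarray | pd.Series,
    n_reads: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw ``n_reads`` from a per-gene count vector without replacement.

    The draw is multivariate hypergeometric, so the boundary n_reads ==
    total returns the original counts exactly, and the subsample always
    sums to ``n_reads``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(np.int64)
    total = int(c.sum())
    if n_reads > total:
        raise ValueError(f"n_reads={n_reads} exceeds total counts {total}")
    if total < 1_000_000_000:
        return rng.multivariate_hypergeometric(c, n_reads, method="marginals")
    # beyond the exact sampler's limit the multinomial approximation is
    # indistinguishable (n_reads << total)
    return rng.multinomial(n_reads, c / total)


def recompute_fpkm(counts: np.ndarray, lengths_nt: np.ndarray) -> np.ndarray:
    """FPKM from a count vector/matrix and gene lengths (nt)."""
    c = np.asarray(counts, dtype=float)
    len_kb = np.asarray(lengths_nt, dtype=float) / 1e3
    if c.ndim == 1:
        total_m = c.sum() / 1e6
        return c / (len_kb * total_m)
    total_m = c.sum(axis=0) / 1e6
    return c / (len_kb[:, None] * total_m[None, :])


def in_silico_pool(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    lengths_nt: pd.Series,
    depth_reads: int,
    n_pools: int = 60,
    seed: int | np.random.Generator = 0,
    conditions: list[str] | None = None,
) -> ExpressionMatrix:
    """Aggregate in-silico pooled profiles per condition.

    All single-nucleus counts of a condition are summed, then ``n_pools``
    independent subsamples of ``depth_reads`` reads are drawn; FPKM is
    recomputed per pool.
    """
    if matrix.counts is None:
        raise ValueError("matrix has no counts layer; pooling needs counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = lengths_nt.loc[matrix.gene_ids].to_numpy()
    conds = conditions or sorted(set(samples.table["condition"]))
    fpkm_cols: dict[str, np.ndarray] = {}
    count_cols: dict[str, np.ndarray] = {}
    for cond in conds:
        members = samples.samples_where(condition=cond, assay_level="single_nucleus")
        if len(members) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 single samples")
        pooled = matrix.counts[members].to_numpy().sum(axis=1)
        if depth_reads > pooled.sum():
            raise ValueError(
                f"depth_reads={depth_reads} exceeds pooled total {int(pooled.sum())}")
        for k in range(n_pools):
            sub = subsample_counts(pooled, depth_reads, rng)
            name = f"Pool_{cond}_{k + 1:02d}"
            count_cols[name] = sub
            fpkm_cols[name] = recompute_fpkm(sub, lengths)
    idx = matrix.gene_ids
    return ExpressionMatrix(pd.DataFrame(fpkm_cols, index=idx),
                            counts=pd.DataFrame(count_cols, index=idx))


def detection_saturation(
    counts: pd.Series,
    lengths_nt: pd.Series,
    depths: list[int],
    reps: int = 10,
    fpkm_min: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> SaturationCurve:
    """Detected-gene count (FPKM >= ``fpkm_min``) vs subsampled depth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = lengths_nt.loc[counts.index].to_numpy()
    c = counts.to_numpy()
    values = []
    for depth in depths:
        vals = []
        for _ in range(reps):
            sub = subsample_counts(c, depth, rng)
            fpkm = recompute_fpkm(sub, lengths)
            vals.append(int((fpkm >= fpkm_min).sum()))
        values.append(np.asarray(vals))
    return SaturationCurve(np.asarray(depths), values, label="detected_genes")


def correlation_saturation(
    matrix: ExpressionMatrix,
    reference: pd.Series,
    set_sizes: tuple[int, ...] = (2, 5, 10, 15, 20, 25, 30, 35),
    reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> SaturationCurve:
    """Pearson r of subset-mean FPKM vs a reference profile, on log2(FPKM+1).

    For each set size, ``reps`` random sample subsets are drawn; their
    per-gene mean FPKM is correlated with ``reference``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max(set_sizes) > matrix.n_samples:
        raise ValueError(
            f"set size {max(set_sizes)} exceeds number of samples ({matrix.n_samples})")
    ref = np.log2(reference.loc[matrix.gene_ids].to_numpy() + 1.0)
    x = matrix.fpkm.to_numpy()
    values = []
    for size in set_sizes:
        vals = []
        for _ in range(reps):
            cols = rng.choice(matrix.n_samples, size=size, replace=False)
            mean_prof = np.log2(x[:, cols].mean(axis=1) + 1.0)
            vals.append(float(np.corrcoef(mean_prof, ref)[0, 1]))
        values.append(np.asarray(vals))
    return SaturationCurve(np.asarray(set_sizes), values, label="correlation")
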