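"""Signed weighted gene co-expression network, from scratch.

The network follows the weighted-correlation-network recipe: pairwise
Pearson correlation s_ij across samples, signed soft-threshold adjacency
a_ij = (0.5 + 0.5 s_ij)^beta, topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with TOM_ii = 1 and connectivity k_i = sum_{j != i} a_ij.  Modules are
branches of the average-linkage tree on 1 - TOM (a simplified dynamic cut
by branch size, coherence and separation), pruned by eigengene
connectivity kME (< 0.3
dropped; a module lacking 5 genes with kME >= 0.5 is disbanded) and merged
when eigengene correlation exceeds 0.75.  Module eigengenes are the first
principal component of the standardized member-gene expression; gene
significance (GS) and module membership (MM = kME) connect genes to sample
traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "NetworkModel",
    "ModuleSet",
    "TraitAssociation",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "kme_table",
    "prune_and_disband",
    "merge_modules",
    "trait_association",
    "export_network",
    "build_modules",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass
class NetworkModel:
    """Correlation, adjacency, TOM and connectivity for a fixed gene order."""

    genes: list[str]
    beta: int
    s: np.ndarray                       # gene x gene Pearson correlation
    a: np.ndarray                       # signed adjacency in [0,1]
    k: np.ndarray                       # connectivity, sum_{j != i} a_ij
    tom: np.ndarray | None = None


@dataclass
class ModuleSet:
    """Module label per gene, eigengenes, kME and merge history."""

    labels: pd.Series                         # gene -> module label or UNASSIGNED
    eigengenes: pd.DataFrame | None = None    # samples x modules
    kme: pd.DataFrame | None = None           # genes x modules
    merge_history: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def module_names(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class TraitAssociation:
    """Gene- and module-level correlations with sample traits."""

    gs: pd.DataFrame                  # genes x traits correlation
    mm: pd.DataFrame                  # genes x modules correlation (kME)
    module_trait_corr: pd.DataFrame   # modules x traits
    module_trait_p: pd.DataFrame      # modules x traits
    module_assignment: dict[str, str]  # module -> trait of most significant assoc.


# ---------------------------------------------------------------------------


def signed_adjacency(matrix: ExpressionMatrix, beta: int = 6,
                     log_transform: bool = True) -> NetworkModel:
    """Signed soft-threshold adjacency a_ij = (0.5 + 0.5 s_ij)^beta.

    Correlation is Pearson across samples on log2(FPKM+1) by default.
    Constant genes (undefined correlation) are excluded with a warning.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = matrix.fpkm.to_numpy().astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    sds = x.std(axis=1)
    keep = sds > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} constant gene(s) from network")
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    s = np.atleast_2d(np.corrcoef(x[keep]))
    s = np.clip(s, -1.0, 1.0)
    a = (0.5 + 0.5 * s) ** beta
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    return NetworkModel(genes=genes, beta=beta, s=s, a=a, k=k)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index: signed R^2 of log10 p(k) on log10 k.

    Connectivities are binned into ``n_bins`` equal-width bins; the bin
    frequency is regressed on the bin-mean connectivity in log-log space.
    The R^2 is signed by the slope (positive slope = anti-scale-free gives a
    negative index).  Returns NaN when fewer than 2 bins are occupied.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 10:
        raise ValueError("need at least 10 positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        means.append(k[sel].mean())
        freqs.append(sel.mean())
    if len(means) < 2:
        return float("nan")
    lx = np.log10(np.asarray(means))
    ly = np.log10(np.asarray(freqs))
    slope, _inter, r, _p, _se = stats.linregress(lx, ly)
    if not np.isfinite(r):
        return 0.0  # flat frequency profile carries no power-law signal
    return float(-np.sign(slope) * r ** 2)


def pick_soft_power(matrix: ExpressionMatrix, powers: list[int] | None = None,
                    target: float = 0.98, n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Lowest power whose scale-free fit index flattens out at ``target``.

    Falls back to the power with the highest index when none reaches it.
    """
    powers = powers or list(range(1, 13))
    rows = []
    for b in powers:
        net = signed_adjacency(matrix, beta=b)
        rows.append({"beta": b, "fit_index": scale_free_fit(net.k, n_bins),
                     "mean_k": float(net.k.mean())})
    table = pd.DataFrame(rows)
    reached = table[table["fit_index"] >= target]
    beta = int(reached["beta"].iloc[0]) if len(reached) else int(
        table.loc[table["fit_index"].idxmax(), "beta"])
    return beta, table


def topological_overlap(net: NetworkModel) -> np.ndarray:
    """Signed topological overlap matrix; also stored on the model."""
    a = net.a
    k = net.k
    # (a@a)_ij includes u == i and u == j (each contributing a_ij since
    # a_ii = 1); removing both and adding back the direct edge a_ij leaves
    # sum_{u != i,j} a_iu a_uj + a_ij = (a@a)_ij - a_ij
    num = a @ a - a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    net.tom = tom
    return tom


# ---------------------------------------------------------------------------
# module detection


def detect_modules(
    net: NetworkModel,
    min_module_size: int = 15,
    max_module_size: int = 80,
    split_gap: float = 0.08,
) -> ModuleSet:
    """Branches of the average-linkage tree on 1 - TOM become modules.

    Simplified dynamic cut, top-down: a branch stops splitting and becomes
    a module when it is no larger than ``max_module_size``, is coherent
    (its merge height is within ``split_gap`` of the median height at
    which its members joined, so it carries no chain of late, loosely
    attached outsiders), and is strictly separated from its parent merge.
    Branches failing these conditions are split further; fragments smaller
    than ``min_module_size`` are shaved to the unassigned pool.  A tree
    with no internal structure (every merge at the same height) yields no
    modules.  Modules are named M1, M2, ... in decreasing size order.
    """
    from scipy.cluster.hierarchy import to_tree

    tom = net.tom if net.tom is not None else topological_overlap(net)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    z = average(squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False))
    root = to_tree(z)
    found: list[list[int]] = []

    # internal merge heights of every subtree, bottom-up
    internal: dict[int, list[float]] = {}

    def collect(node) -> list[float]:
        if node.is_leaf():
            internal[node.id] = []
            return internal[node.id]
        below = collect(node.left) + collect(node.right) + [node.dist]
        internal[node.id] = below
        return below

    collect(root)

    def coherent(node) -> bool:
        """A branch is one module when its merge height is close to the
        typical height at which its members joined (no chain of late,
        loosely attached outsiders)."""
        below = internal[node.left.id] + internal[node.right.id]
        if not below:
            return True
        return node.dist - float(np.median(below)) <= split_gap

    def recurse(node, parent_dist: float) -> None:
        if node.get_count() < min_module_size or node.is_leaf():
            return
        separated = parent_dist - node.dist > 1e-9
        if (node.get_count() <= max_module_size and coherent(node)
                and separated and node is not root):
            found.append(node.pre_order(lambda leaf: leaf.id))
            return
        recurse(node.left, node.dist)
        recurse(node.right, node.dist)

    recurse(root, float("inf"))
    found.sort(key=len, reverse=True)
    labels = pd.Series(UNASSIGNED, index=net.genes, name="module")
    for i, idxs in enumerate(found):
        labels.iloc[idxs] = f"M{i + 1}"
    return ModuleSet(labels=labels)


def module_eigengene(matrix: ExpressionMatrix, members: list[str],
                     log_transform: bool = True) -> pd.Series:
    """First principal component over samples of standardized member genes.

    The sign is oriented to correlate positively with the module's mean
    standardized expression.
    """
    if len(members) < 2:
        raise ValueError("module needs at least 2 genes")
    x = matrix.fpkm.loc[members].to_numpy().astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    sds = x.std(axis=1)
    x = x[sds > 0]
    if x.shape[0] < 1:
        raise ValueError("degenerate module: all member genes constant")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.sample_ids, name="eigengene")


def _eigengene_frame(matrix: ExpressionMatrix, modules: ModuleSet,
                     log_transform: bool = True) -> pd.DataFrame:
    cols = {}
    for m in modules.module_names:
        cols[m] = module_eigengene(matrix, modules.members(m), log_transform)
    return pd.DataFrame(cols, index=matrix.sample_ids)


def kme_table(matrix: ExpressionMatrix, eigengenes: pd.DataFrame,
              log_transform: bool = True) -> pd.DataFrame:
    """kME: Pearson correlation of each gene with each module eigengene."""
    x = matrix.fpkm.to_numpy().astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    xz = x - x.mean(axis=1, keepdims=True)
    xs = xz.std(axis=1)
    e = eigengenes.to_numpy()
    ez = e - e.mean(axis=0, keepdims=True)
    es = ez.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xz @ ez) / (len(matrix.sample_ids)) / np.outer(xs, es)
    return pd.DataFrame(np.clip(corr, -1, 1), index=matrix.gene_ids,
                        columns=eigengenes.columns)


def prune_and_disband(
    matrix: ExpressionMatrix,
    modules: ModuleSet,
    min_kme_to_stay: float = 0.3,
    min_core_kme: float = 0.5,
    core_n: int = 5,
    max_iter: int = 10,
    log_transform: bool = True,
) -> ModuleSet:
    """Iterate kME pruning to a fixed point (at most ``max_iter`` rounds).

    Members with kME < ``min_kme_to_stay`` to their own eigengene are
    dropped; a module without at least ``core_n`` members at kME >=
    ``min_core_kme`` is disbanded (its genes return to the unassigned pool).
    """
    labels = modules.labels.copy()
    for _ in range(max_iter):
        active = sorted(set(labels) - {UNASSIGNED})
        if not active:
            break
        eig = _eigengene_frame(matrix, ModuleSet(labels=labels), log_transform)
        kme = kme_table(matrix, eig, log_transform)
        changed = False
        for m in active:
            members = list(labels.index[labels == m])
            own = kme.loc[members, m]
            drop = own.index[own < min_kme_to_stay]
            if len(drop):
                labels[drop] = UNASSIGNED
                changed = True
                members = [g for g in members if g not in set(drop)]
            core = (kme.loc[members, m] >= min_core_kme).sum() if members else 0
            if core < core_n or len(members) < 2:
                labels[labels == m] = UNASSIGNED
                changed = True
        if not changed:
            break
    result = ModuleSet(labels=labels, merge_history=list(modules.merge_history))
    if result.module_names:
        result.eigengenes = _eigengene_frame(matrix, result, log_transform)
        result.kme = kme_table(matrix, result.eigengenes, log_transform)
    return result


def merge_modules(
    matrix: ExpressionMatrix,
    modules: ModuleSet,
    merge_corr: float = 0.75,
    log_transform: bool = True,
) -> ModuleSet:
    """Merge modules whose eigengenes correlate strictly above ``merge_corr``.

    Greedy: repeatedly merge the most-correlated pair, recomputing
    eigengenes, until no pair exceeds the threshold.  History records each
    merge as a tuple of the absorbed module names.
    """
    labels = modules.labels.copy()
    history = list(modules.merge_history)
    while True:
        names = sorted(set(labels) - {UNASSIGNED})
        if len(names) < 2:
            break
        eig = _eigengene_frame(matrix, ModuleSet(labels=labels), log_transform)
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_corr:  # "above 0.75": exactly 0.75 not merged
            break
        a, b = names[i], names[j]
        labels[labels == b] = a
        history.append((a, b))
    result = ModuleSet(labels=labels, merge_history=history)
    if result.module_names:
        result.eigengenes = _eigengene_frame(matrix, result, log_transform)
        result.kme = kme_table(matrix, result.eigengenes, log_transform)
    return result


def build_modules(
    matrix: ExpressionMatrix,
    beta: int = 6,
    min_module_size: int = 15,
    min_kme_to_stay: float = 0.3,
    min_core_kme: float = 0.5,
    core_n: int = 5,
    merge_corr: float = 0.75,
    max_module_size: int = 80,
    split_gap: float = 0.08,
) -> tuple[NetworkModel, ModuleSet]:
    """Full pipeline: adjacency -> TOM -> detect -> prune -> merge."""
    net = signed_adjacency(matrix, beta=beta)
    topological_overlap(net)
    sub = matrix.subset_genes(net.genes)
    modules = detect_modules(net, min_module_size=min_module_size,
                             max_module_size=max_module_size, split_gap=split_gap)
    modules = prune_and_disband(sub, modules, min_kme_to_stay, min_core_kme, core_n)
    modules = merge_modules(sub, modules, merge_corr)
    return net, modules


# ---------------------------------------------------------------------------
# traits and export


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation p of a Pearson correlation at sample size n."""
    r = np.clip(np.asarray(r, dtype=float), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def trait_association(
    matrix: ExpressionMatrix,
    modules: ModuleSet,
    subgroups: pd.Series,
    log_transform: bool = True,
) -> TraitAssociation:
    """Point-biserial correlation of eigengenes and genes with subgroup
    indicators; each module is assigned to its most significant trait."""
    if modules.eigengenes is None:
        raise ValueError("modules have no eigengenes; run prune/merge first")
    subgroups = subgroups.loc[matrix.sample_ids]
    levels = sorted(set(subgroups))
    if len(levels) < 2:
        raise ValueError("need at least 2 subgroups")
    indicators = pd.DataFrame(
        {lv: (subgroups == lv).astype(float) for lv in levels}, index=matrix.sample_ids)
    n = matrix.n_samples
    gs = kme_table(matrix, indicators, log_transform)
    eig = modules.eigengenes
    mt_corr = pd.DataFrame(index=eig.columns, columns=levels, dtype=float)
    for m in eig.columns:
        for lv in levels:
            mt_corr.loc[m, lv] = float(np.corrcoef(eig[m], indicators[lv])[0, 1])
    mt_p = pd.DataFrame(_corr_pvalue(mt_corr.to_numpy(), n),
                        index=mt_corr.index, columns=mt_corr.columns)
    assignment = {m: mt_p.loc[m].idxmin() for m in mt_p.index}
    mm = modules.kme if modules.kme is not None else kme_table(matrix, eig, log_transform)
    return TraitAssociation(gs=gs, mm=mm, module_trait_corr=mt_corr,
                            module_trait_p=mt_p, module_assignment=assignment)


def export_network(
    modules: ModuleSet,
    net: NetworkModel,
    edge_threshold: float,
    edge_path,
    node_path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node attribute tables for graph viewers (deterministic order).

    Edges are intra-module gene pairs with TOM weight above the threshold.
    """
    if net.tom is None:
        raise ValueError("network has no TOM; run topological_overlap first")
    pos = {g: i for i, g in enumerate(net.genes)}
    edges = []
    for m in modules.module_names:
        members = sorted(modules.members(m))
        for i, g1 in enumerate(members):
            for g2 in members[i + 1:]:
                w = net.tom[pos[g1], pos[g2]]
                if w > edge_threshold:
                    edges.append((g1, g2, float(w), m))
    edge_df = pd.DataFrame(edges, columns=["gene1", "gene2", "tom", "module"])
    nodes = []
    for g in modules.labels.index:
        m = modules.labels[g]
        kme = (float(modules.kme.loc[g, m])
               if modules.kme is not None and m in getattr(modules.kme, "columns", [])
               else np.nan)
        nodes.append((g, m, kme))
    node_df = pd.DataFrame(nodes, columns=["gene", "module", "kme"])
    edge_df.to_csv(edge_path, sep="\t", index=False)
    node_df.to_csv(node_path, sep="\t", index=False)
    return edge_df, node_df
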