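"""Synthetic single-nucleus, pooled and bulk cardiomyocyte expression data.

The generator emulates the statistical structure of single-nucleus RNA-seq
of failing (TAC, transverse aortic constriction) versus non-failing (Sham)
mouse hearts, with full ground truth for every downstream stage:

* two conditions, each splitting into two subgroups of nuclei, separated by
  subgroup-specific gene programs strong enough that sample clustering on
  correlation distance shows four branches;
* a TAC-shared stress program so pairwise correlations among TAC nuclei
  exceed those among Sham nuclei, and more genes pass the expression gate
  in TAC than in Sham;
* three planted co-expression modules with subgroup-specific 4-fold
  activation and per-nucleus activity jitter whose gene loadings define a
  planted hub gene per module;
* core genes expressed at very high level in every nucleus with low
  between-nucleus variance;
* two marker panels whose joint activation is confined to a fraction of
  nuclei of one TAC subgroup (the quadrant-analysis ground truth);
* nuclear-retained lincRNA genes that pass the expression gate in nuclei
  but are diluted below it in matched bulk profiles;
* a transcript catalog of coding and noncoding sequences for the
  coding-potential classifier.

Counts are negative binomial around the per-nucleus mean, thinned by a
logistic-in-log-mean Bernoulli dropout so penetrance rises with mean
expression.  FPKM = count / (gene length in kb x sample total in millions).
All randomness flows from one ``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotationTable, GeneSetPanel, SampleTable

__all__ = [
    "ModuleSpec",
    "PanelSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_nuclei",
    "simulate_bulk",
    "simulate_transcript_catalog",
    "default_panels",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: activated ``log2_activation``-fold
    (log2 scale) in the named subgroups, with per-nucleus activity jitter."""

    name: str
    size: int
    active_subgroups: tuple[str, ...]
    log2_activation: float = 2.0


@dataclass(frozen=True)
class PanelSpec:
    """A marker panel; ``co_activation_fraction`` maps subgroup name to the
    fraction of that subgroup's nuclei in which the panel is switched on."""

    name: str
    role: str
    size: int
    co_activation_fraction: Mapping[str, float] = field(default_factory=dict)


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec("healthy", 50, ("Sham_A",), 2.0),
        ModuleSpec("disease_1", 50, ("TAC_A",), 2.0),
        ModuleSpec("disease_2", 50, ("TAC_B",), 2.0),
    )


def _default_panels() -> tuple[PanelSpec, ...]:
    frac = {"Sham_A": 0.0, "Sham_B": 0.0, "TAC_A": 0.6, "TAC_B": 0.0}
    return (
        PanelSpec("proliferation", "proliferation", 8, frac),
        PanelSpec("negative_regulators", "negative_regulators", 8, frac),
    )


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    n_genes: int = 1200
    n_nuclei_per_subgroup: int = 20
    conditions: tuple[str, ...] = ("Sham", "TAC")
    subgroups_per_condition: int = 2
    module_specs: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    core_gene_count: int = 6
    ballast_gene_count: int = 80      # constitutive continuum pinning the FPKM scale
    panel_specs: tuple[PanelSpec, ...] = field(default_factory=_default_panels)
    linc_count: int = 60
    # dedicated differential-expression ground truth: genes at a clean
    # 4-fold (log2 = 2) difference between the two TAC subgroups
    de_gene_count: int = 60
    de_log2fc: float = 2.0
    nuclear_retention_factor: float = 10.0
    dropout_midpoint: float = 2.5
    dropout_steepness: float = 2.5
    nb_dispersion: float = 0.3
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0
    # generator internals beyond the headline knobs
    # heterogeneity genes toggle between an off (base) and an on
    # (base + amplitude) state per subgroup: bounded, mass-neutral
    # presence/absence heterogeneity that separates the four branches
    het_on_prob: float = 0.5          # probability a het gene is on in a subgroup
    # condition-specific on-probability override: failing (TAC) nuclei
    # activate a broader transcriptome than Sham, so more genes pass the
    # expression gate in TAC
    condition_on_prob: Mapping[str, float] = field(
        default_factory=lambda: {"Sham": 0.42, "TAC": 0.58})
    het_amp_range: tuple[float, float] = (5.5, 8.5)  # log2 on-state amplitude
    # probability that the second subgroup of a condition copies the first
    # subgroup's on/off state per gene (the TAC stress response is partly
    # shared by both TAC subgroups, so cross-TAC correlations exceed Sham's)
    condition_share: Mapping[str, float] = field(
        default_factory=lambda: {"Sham": 0.0, "TAC": 0.15})
    # per-condition multiplier on the dropout midpoint: TAC nuclei detect a
    # broader transcriptome (more expressed genes, tighter correlations)
    condition_midpoint_factor: Mapping[str, float] = field(
        default_factory=lambda: {"Sham": 1.0, "TAC": 1.0})
    het_fraction: float = 0.85         # heterogeneity share of background genes
    module_activity_sd: float = 2.0   # log2 sd of per-nucleus module activity
    panel_on_fpkm: float = 8.0
    panel_off_fpkm: float = 0.2
    library_size_mean: float = 8.5e6  # mapped-read scale of each nucleus
    library_size_sigma: float = 0.35  # log-normal sigma of library sizes
    n_batches: int = 2

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_nuclei_per_subgroup": self.n_nuclei_per_subgroup,
            "subgroups_per_condition": self.subgroups_per_condition,
            "core_gene_count": self.core_gene_count,
            "ballast_gene_count": self.ballast_gene_count,
            "linc_count": self.linc_count,
            "de_gene_count": self.de_gene_count,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("nuclear_retention_factor", "dropout_midpoint", "nb_dispersion",
                     "module_activity_sd", "panel_on_fpkm", "panel_off_fpkm",
                     "library_size_mean", "library_size_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.nuclear_retention_factor < 1:
            raise ValueError(f"nuclear_retention_factor must be >= 1, got {self.nuclear_retention_factor!r}")
        if not 0.0 <= self.het_on_prob <= 1.0:
            raise ValueError(f"het_on_prob must be in [0,1], got {self.het_on_prob!r}")
        for cond, share in self.condition_share.items():
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"condition_share[{cond!r}] must be in [0,1], got {share!r}")
        alo, ahi = self.het_amp_range
        if not (np.isfinite(alo) and np.isfinite(ahi) and 0 <= alo <= ahi):
            raise ValueError(f"het_amp_range must satisfy 0 <= lo <= hi, got {self.het_amp_range!r}")
        # dropout_steepness may be +inf (dropout switched hard); not negative/NaN
        if math.isnan(self.dropout_steepness) or self.dropout_steepness < 0:
            raise ValueError(f"dropout_steepness must be >= 0, got {self.dropout_steepness!r}")
        for p in self.panel_specs:
            for sg, f in p.co_activation_fraction.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(
                        f"co_activation_fraction for panel {p.name!r} subgroup {sg!r} "
                        f"must be in [0,1], got {f!r}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"gene_length_range must satisfy 0 < lo <= hi, got {self.gene_length_range!r}")
        needed = (self.core_gene_count + self.ballast_gene_count
                  + sum(m.size for m in self.module_specs)
                  + sum(p.size for p in self.panel_specs) + self.linc_count
                  + self.de_gene_count)
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for planted structure ({needed} genes)")

    @property
    def subgroup_names(self) -> list[str]:
        letters = [chr(ord("A") + i) for i in range(self.subgroups_per_condition)]
        return [f"{c}_{l}" for c in self.conditions for l in letters]


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment."""

    subgroup_of_sample: dict[str, str]
    module_of_gene: dict[str, str]
    core_genes: tuple[str, ...]
    panel_members: dict[str, tuple[str, ...]]
    coexpressing_samples: dict[tuple[str, str], tuple[str, ...]]
    linc_genes: tuple[str, ...]
    mean_fpkm: pd.DataFrame          # gene x subgroup designed means
    gene_lengths: pd.Series          # nt
    null_genes: tuple[str, ...]      # identical mean in every subgroup
    de_genes: dict[str, str]         # DE ground truth: gene -> up-subgroup
    module_loadings: dict[str, float]
    hub_of_module: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        mods: dict[str, list[str]] = {}
        for g, m in self.module_of_gene.items():
            mods.setdefault(m, []).append(g)
        seen: set[str] = set()
        for m, genes in mods.items():
            if seen & set(genes):
                raise ValueError("module gene sets are not disjoint")
            seen |= set(genes)
        subgroup_samples: dict[str, set[str]] = {}
        for s, sg in self.subgroup_of_sample.items():
            subgroup_samples.setdefault(sg, set()).add(s)


# ---------------------------------------------------------------------------


def _dropout_probability(mean_fpkm: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Logistic-in-log-mean dropout: p = 1 / (1 + (mean/midpoint)^steepness)."""
    if midpoint <= 0:
        return np.zeros_like(mean_fpkm, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(mean_fpkm > 0, mean_fpkm / midpoint, 0.0)
        if np.isinf(steepness):
            return np.where(ratio > 1.0, 0.0, np.where(ratio < 1.0, 1.0, 0.5))
        powed = np.power(ratio, steepness, where=ratio > 0,
                         out=np.zeros_like(ratio))
        return 1.0 / (1.0 + powed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial with var = mu + d*mu^2; d == 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    poisson = dispersion <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson & (mean > 0)
    if nb.any():
        size = 1.0 / dispersion[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_nuclei(config: SimConfig) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Simulate the single-nucleus experiment described by ``config``.

    Returns the FPKM+count matrix, the per-sample metadata table and the
    planted ground truth.  Deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subgroups = config.subgroup_names
    n_per = config.n_nuclei_per_subgroup

    samples: list[str] = []
    subgroup_of_sample: dict[str, str] = {}
    batches: dict[str, str] = {}
    for sg in subgroups:
        for i in range(n_per):
            s = f"{sg}_{i + 1:02d}"
            samples.append(s)
            subgroup_of_sample[s] = sg
            batches[s] = f"batch{(i % config.n_batches) + 1}"

    # --- gene roles -------------------------------------------------------
    gene_ids: list[str] = []
    core_genes = [f"core_{i + 1:03d}" for i in range(config.core_gene_count)]
    gene_ids += core_genes
    ballast_genes = [f"hk_{i + 1:03d}" for i in range(config.ballast_gene_count)]
    gene_ids += ballast_genes
    module_of_gene: dict[str, str] = {}
    module_loadings: dict[str, float] = {}
    hub_of_module: dict[str, str] = {}
    for spec in config.module_specs:
        members = [f"mod_{spec.name}_{i + 1:03d}" for i in range(spec.size)]
        gene_ids += members
        loadings = np.concatenate([[1.0], rng.uniform(0.6, 0.88, size=spec.size - 1)])
        for g, w in zip(members, loadings):
            module_of_gene[g] = spec.name
            module_loadings[g] = float(w)
        hub_of_module[spec.name] = members[0]
    panel_members: dict[str, tuple[str, ...]] = {}
    for spec in config.panel_specs:
        members = tuple(f"panel_{spec.name}_{i + 1:02d}" for i in range(spec.size))
        panel_members[spec.name] = members
        gene_ids += list(members)
    linc_genes = tuple(f"linc_{i + 1:03d}" for i in range(config.linc_count))
    gene_ids += list(linc_genes)
    de_genes = [f"de_{i + 1:03d}" for i in range(config.de_gene_count)]
    gene_ids += de_genes
    n_background = config.n_genes - len(gene_ids)
    n_het = int(round(n_background * config.het_fraction))
    het_genes = [f"het_{i + 1:04d}" for i in range(n_het)]
    null_genes = tuple(f"null_{i + 1:04d}" for i in range(n_background - n_het))
    gene_ids += het_genes + list(null_genes)

    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                     size=len(gene_ids)),
        index=gene_ids, name="length")

    # --- designed log2 mean FPKM per subgroup -----------------------------
    log2_mean = pd.DataFrame(0.0, index=gene_ids, columns=subgroups)
    # core gene levels are assigned adaptively below so the transcriptome's
    # surviving FPKM mass is self-consistent (sums to ~1e6 x kb)
    core_rel = rng.uniform(1.0, 2.5, size=config.core_gene_count)
    # housekeeping continuum: constant across subgroups, log-uniform in
    # abundance; carries most of the library mass so realized FPKM stays on
    # the designed scale when low-abundance genes drop out
    log2_mean.loc[ballast_genes, :] = rng.uniform(
        np.log2(4), np.log2(32), size=config.ballast_gene_count)[:, None]
    for spec in config.module_specs:
        members = [g for g, m in module_of_gene.items() if m == spec.name]
        base = rng.normal(np.log2(20.0), 0.3, size=len(members))
        base[0] = np.log2(100.0)  # hub: abundant, detected in every nucleus
        for sg in subgroups:
            shift = spec.log2_activation if sg in spec.active_subgroups else 0.0
            log2_mean.loc[members, sg] = base + shift
    for name, members in panel_members.items():
        log2_mean.loc[list(members), :] = np.log2(config.panel_off_fpkm)
    # wide abundance spread: the lower tail is diluted below the gate in
    # bulk (nuclear-retained), the upper tail remains detectable there
    log2_mean.loc[list(linc_genes), :] = rng.normal(
        np.log2(40.0), 1.2, size=config.linc_count)[:, None]
    # DE ground-truth genes: first half up in the first TAC subgroup,
    # second half up in the second
    de_base = rng.normal(np.log2(10.0), 0.5, size=config.de_gene_count)
    log2_mean.loc[de_genes, :] = de_base[:, None]
    tac_sgs = [sg for sg in subgroups if sg.startswith("TAC")]
    de_up_subgroup: dict[str, str] = {}
    if len(tac_sgs) >= 2:
        half = config.de_gene_count // 2
        log2_mean.loc[de_genes[:half], tac_sgs[0]] += config.de_log2fc
        log2_mean.loc[de_genes[half:], tac_sgs[1]] += config.de_log2fc
        de_up_subgroup = {g: tac_sgs[0] for g in de_genes[:half]}
        de_up_subgroup.update({g: tac_sgs[1] for g in de_genes[half:]})
    null_base = rng.normal(1.5, 1.0, size=len(null_genes))
    log2_mean.loc[list(null_genes), :] = null_base[:, None]
    # het genes sit near the detection floor when off, so the on/off states
    # dominate the shared mean profile in sample-sample correlations
    het_base = rng.normal(0.5, 0.5, size=n_het)
    log2_mean.loc[het_genes, :] = het_base[:, None]
    # heterogeneity genes: per-subgroup on/off states with a bounded
    # on-state amplitude.  On/off assignments are independent between the
    # two Sham subgroups; each TAC gene's state is copied from the first
    # TAC subgroup to the second with probability condition_share["TAC"],
    # modelling the partly shared stress response.
    amp = rng.uniform(*config.het_amp_range, size=n_het)
    on = {}
    for cond in config.conditions:
        cond_sgs = [sg for sg in subgroups if sg.startswith(cond)]
        share = config.condition_share.get(cond, 0.0)
        on_prob = config.condition_on_prob.get(cond, config.het_on_prob)
        lead = rng.random(n_het) < on_prob
        on[cond_sgs[0]] = lead
        for sg in cond_sgs[1:]:
            copy = rng.random(n_het) < share
            own = rng.random(n_het) < on_prob
            on[sg] = np.where(copy, lead, own)
    # het genes never carry a single-subgroup pattern: that signature is
    # reserved for the planted modules, which would otherwise be absorbed
    # into indistinguishable heterogeneity clusters
    state = np.column_stack([on[sg] for sg in subgroups])
    single = state.sum(axis=1) == 1
    if single.any():
        extra = rng.integers(0, len(subgroups), size=int(single.sum()))
        lone = state[single].argmax(axis=1)
        extra = np.where(extra == lone, (extra + 1) % len(subgroups), extra)
        rows = np.flatnonzero(single)
        state[rows, extra] = True
    for j, sg in enumerate(subgroups):
        log2_mean.loc[het_genes, sg] = (log2_mean.loc[het_genes, sg].to_numpy()
                                        + np.where(state[:, j], amp, 0.0))

    mean_fpkm = 2.0 ** log2_mean

    # --- per-nucleus means ------------------------------------------------
    sample_idx = {s: j for j, s in enumerate(samples)}
    per_nucleus_log2 = np.empty((len(gene_ids), len(samples)))
    for s in samples:
        per_nucleus_log2[:, sample_idx[s]] = log2_mean[subgroup_of_sample[s]].to_numpy()

    # module activity: a per-nucleus latent co-fluctuation shared by all
    # member genes in every nucleus (scaled by gene loadings, hub highest),
    # on top of the subgroup-specific activation shift
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for spec in config.module_specs:
        members = [g for g, m in module_of_gene.items() if m == spec.name]
        rows = [gene_pos[g] for g in members]
        w = np.array([module_loadings[g] for g in members])
        theta = rng.normal(0.0, config.module_activity_sd, size=len(samples))
        per_nucleus_log2[np.ix_(rows, range(len(samples)))] += np.outer(w, theta)

    # panel co-activation confined to chosen nuclei of designated subgroups
    coactive_by_subgroup: dict[str, list[str]] = {}
    fractions: dict[str, float] = {}
    for spec in config.panel_specs:
        for sg, f in spec.co_activation_fraction.items():
            fractions[sg] = max(fractions.get(sg, 0.0), f)
    for sg, f in fractions.items():
        sg_samples = [s for s in samples if subgroup_of_sample[s] == sg]
        k = int(round(f * len(sg_samples)))
        chosen = list(rng.choice(sg_samples, size=k, replace=False)) if k else []
        coactive_by_subgroup[sg] = chosen
    coexpressing: dict[tuple[str, str], tuple[str, ...]] = {}
    panel_names = [p.name for p in config.panel_specs]
    all_coactive: set[str] = set()
    for spec in config.panel_specs:
        rows = [gene_pos[g] for g in panel_members[spec.name]]
        for sg, f in spec.co_activation_fraction.items():
            if f <= 0:
                continue
            for s in coactive_by_subgroup[sg]:
                per_nucleus_log2[rows, sample_idx[s]] = np.log2(config.panel_on_fpkm)
                all_coactive.add(s)
    for i, px in enumerate(panel_names):
        for py in panel_names[i + 1:]:
            shared = [s for s in samples if s in all_coactive]
            coexpressing[(px, py)] = tuple(shared)

    per_nucleus_fpkm = 2.0 ** per_nucleus_log2

    # --- counts, dropout, FPKM -------------------------------------------
    lib_sizes = config.library_size_mean * rng.lognormal(
        -0.5 * config.library_size_sigma ** 2, config.library_size_sigma,
        size=len(samples))
    len_kb = lengths.to_numpy()[:, None] / 1e3
    # per-condition detection-breadth contrast acts on the background
    # (het/null) genes; the strongly expressed planted structure (core,
    # modules, panels, lincs) is robustly detected in either condition
    factor_of_sample = np.array([
        config.condition_midpoint_factor.get(subgroup_of_sample[s].split("_")[0], 1.0)
        for s in samples])
    background_mask = np.array([g.startswith(("het_", "null_")) for g in gene_ids])
    # dropout reflects a gene's typical abundance in the nucleus's subgroup
    # (its detectability), not the instantaneous activity-jittered level
    subgroup_mean_cols = np.column_stack([
        mean_fpkm[subgroup_of_sample[s]].to_numpy() for s in samples])
    detect_basis = np.where(
        np.isin(gene_ids, [g for p_ in panel_members.values() for g in p_])[:, None],
        per_nucleus_fpkm, subgroup_mean_cols)
    p_drop = np.empty_like(per_nucleus_fpkm)
    for j in range(len(samples)):
        mid = config.dropout_midpoint * factor_of_sample[j]
        col_bg = _dropout_probability(detect_basis[:, j], mid,
                                      config.dropout_steepness)
        col_fg = _dropout_probability(detect_basis[:, j], config.dropout_midpoint,
                                      config.dropout_steepness)
        p_drop[:, j] = np.where(background_mask, col_bg, col_fg)
    # FPKM is compositional: the realised value of every gene equals its
    # designed value times 1e6 / (surviving designed mass x kb).  The core
    # genes are the free mass reservoir: their level is set so the mean
    # nucleus's surviving mass is exactly 1e6, which puts realised FPKM on
    # the designed scale and makes every threshold literal.
    core_rows = [gene_pos[g] for g in core_genes]
    noncore = np.ones(len(gene_ids), dtype=bool)
    noncore[core_rows] = False
    rest_mass = (per_nucleus_fpkm[noncore] * len_kb[noncore]
                 * (1.0 - p_drop[noncore])).sum(axis=0)
    core_budget = 1e6 - float(rest_mass.mean())
    if core_budget < 1e5:
        raise RuntimeError(
            "non-core transcriptome mass leaves no room for core genes; "
            "reduce heterogeneity amplitudes or gene count")
    core_len_kb = len_kb[core_rows, 0]
    core_fpkm = core_budget * core_rel / float((core_rel * core_len_kb).sum())
    per_nucleus_fpkm[core_rows, :] = core_fpkm[:, None]
    p_drop[core_rows, :] = 0.0
    mean_fpkm.iloc[core_rows, :] = core_fpkm[:, None]
    expected = per_nucleus_fpkm * len_kb * (lib_sizes[None, :] / 1e6)
    dispersion = np.full(len(gene_ids), config.nb_dispersion)
    dispersion[[gene_pos[g] for g in core_genes]] = 0.02
    # hub genes track the module activity with minimal intrinsic noise
    dispersion[[gene_pos[h] for h in hub_of_module.values()]] = 0.05
    counts = _nb_draw(rng, expected, dispersion[:, None])
    keep = rng.random(counts.shape) >= p_drop
    counts = np.where(keep, counts, 0)

    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise RuntimeError("a simulated nucleus has zero total counts; "
                           "raise expression levels or library size")
    fpkm = counts / (len_kb * (totals[None, :] / 1e6))

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=samples),
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples))
    sample_table = SampleTable(pd.DataFrame({
        "sample_id": samples,
        "condition": [subgroup_of_sample[s].split("_")[0] for s in samples],
        "batch": [batches[s] for s in samples],
        "assay_level": "single_nucleus",
        "subgroup": [subgroup_of_sample[s] for s in samples],
    }))
    truth = GroundTruth(
        subgroup_of_sample=subgroup_of_sample,
        module_of_gene=module_of_gene,
        core_genes=tuple(core_genes),
        panel_members=panel_members,
        coexpressing_samples=coexpressing,
        linc_genes=linc_genes,
        mean_fpkm=mean_fpkm,
        gene_lengths=lengths,
        null_genes=null_genes,
        de_genes=de_up_subgroup,
        module_loadings=module_loadings,
        hub_of_module=hub_of_module,
        seed=config.seed,
    )
    return matrix, sample_table, truth


def default_panels(truth: GroundTruth, roles: Mapping[str, str] | None = None) -> list[GeneSetPanel]:
    """Ground-truth marker panels as GeneSetPanel objects."""
    roles = roles or {}
    return [GeneSetPanel(name, roles.get(name, name), members)
            for name, members in truth.panel_members.items()]


# ---------------------------------------------------------------------------
# bulk


def simulate_bulk(
    truth: GroundTruth,
    mixing: Mapping[str, float],
    cytoplasmic_amplification: float,
    n_replicates: int = 6,
    replicate_dispersion: float = 0.02,
    background_marker_fpkm: float = 50.0,
) -> ExpressionMatrix:
    """Matched bulk left-ventricle profiles from the same ground truth.

    The cardiomyocyte ("CM") component is the condition-average nuclear mean
    profile with every non-linc gene scaled by ``cytoplasmic_amplification``
    (cytoplasmic mRNA dominates bulk libraries; nuclear-retained lincRNAs do
    not benefit).  Other cell types contribute deterministic background
    signatures with their own marker genes.  The mixture is renormalized to
    the nuclear library scale, so lincRNAs that pass the expression gate in
    nuclei fall below it in bulk.
    """
    fracs = dict(mixing)
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError(f"mixing fractions must sum to 1, got {sum(fracs.values())!r}")
    if cytoplasmic_amplification < 1:
        raise ValueError(f"cytoplasmic_amplification must be >= 1, got {cytoplasmic_amplification!r}")
    genes = list(truth.mean_fpkm.index)
    linc_mask = np.isin(genes, list(truth.linc_genes))
    conditions = sorted({sg.split("_")[0] for sg in truth.mean_fpkm.columns})
    rng = np.random.default_rng((truth.seed + 7919) % 2**31)

    background_profiles: dict[str, np.ndarray] = {}
    for ct in fracs:
        if ct == "CM":
            continue
        ct_rng = np.random.default_rng(
            (truth.seed * 1000003 + abs(hash(ct)) % 65521) % 2**31)
        profile = 2.0 ** ct_rng.normal(0.0, 1.0, size=len(genes))
        markers = ct_rng.choice(len(genes), size=max(10, len(genes) // 40), replace=False)
        profile[markers] = background_marker_fpkm
        profile[linc_mask] *= 0.1  # nuclear lincs not exported to other cell types
        background_profiles[ct] = profile

    cols = {}
    for cond in conditions:
        sub_cols = [c for c in truth.mean_fpkm.columns if c.startswith(cond)]
        cm_nuclear = truth.mean_fpkm[sub_cols].mean(axis=1).to_numpy()
        nuclear_total = cm_nuclear.sum()
        cm_bulk = cm_nuclear.copy()
        cm_bulk[~linc_mask] *= cytoplasmic_amplification
        mixed = np.zeros(len(genes))
        for ct, f in fracs.items():
            mixed += f * (cm_bulk if ct == "CM" else background_profiles[ct])
        mixed *= nuclear_total / mixed.sum()  # library-size renormalization
        for r in range(n_replicates):
            if replicate_dispersion > 0:
                noisy = _nb_draw(rng, mixed * 100.0, replicate_dispersion) / 100.0
            else:
                noisy = mixed
            cols[f"Bulk_{cond}_{r + 1:02d}"] = noisy
    return ExpressionMatrix(pd.DataFrame(cols, index=genes))


# ---------------------------------------------------------------------------
# transcript catalog

_STOPS = ("TAA", "TAG", "TGA")
# codon usage biased toward abundant mammalian codons (coding transcripts)
_BIASED_CODONS = [
    "GAG", "AAG", "CTG", "GCC", "GAC", "GTG", "CAG", "ATC", "AAC", "TTC",
    "ACC", "TCC", "GGC", "ATG", "TAC", "CAC", "CCC", "CGC", "AGC", "TGC",
]


def _random_seq(rng: np.random.Generator, length: int, p: Sequence[float] | None = None) -> str:
    bases = np.array(list("ACGT"))
    return "".join(rng.choice(bases, size=length, p=p))


def _kill_long_orfs(seq: str, rng: np.random.Generator, max_orf: int = 240) -> str:
    """Mutate in stop codons until no sense-strand ORF exceeds ``max_orf`` nt."""
    from .lincfilter import longest_orf  # local import avoids cycle at module load

    seq = list(seq)
    for _ in range(200):
        size, _cov, start = longest_orf("".join(seq), return_start=True)
        if size <= max_orf:
            break
        pos = start + 3 * int(rng.integers(1, size // 3 - 1))
        stop = _STOPS[int(rng.integers(3))]
        seq[pos:pos + 3] = list(stop)
    return "".join(seq)


def simulate_transcript_catalog(
    config: SimConfig,
    n_coding: int = 500,
    n_noncoding: int = 500,
) -> tuple[dict[str, str], GeneAnnotationTable, dict[str, str]]:
    """Coding and noncoding transcript sequences with annotation and labels.

    Coding transcripts carry a planted long ORF built from biased codon
    usage; noncoding transcripts have skewed per-transcript base composition
    and no ORF longer than 240 nt.  Lengths are log-uniform in 100-5000 nt
    so the 200 bp length filter is exercised.  Coordinates are 0-based
    half-open on synthetic chromosomes; strands alternate.
    """
    config.validate()
    rng = np.random.default_rng((config.seed + 104729) % 2**31)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    rows = []
    cursor: dict[str, int] = {}

    def place(tx_id: str, length: int, i: int, biotype: str) -> None:
        chrom = f"chrS{(i % 4) + 1}"
        start = cursor.get(chrom, 1000)
        end = start + length
        cursor[chrom] = end + int(rng.integers(200, 2000))
        strand = "+" if i % 2 == 0 else "-"
        if length >= 400 and rng.random() < 0.5:
            split = int(rng.integers(100, length - 100))
            intron = int(rng.integers(80, 500))
            exons = [(start, start + split), (start + split + intron, end + intron)]
            end = end + intron
        else:
            exons = [(start, end)]
        rows.append({"gene_id": tx_id, "chrom": chrom, "start": exons[0][0],
                     "end": exons[-1][1], "strand": strand, "biotype": biotype,
                     "exons": exons, "length": length})

    for i in range(n_coding):
        total = int(round(10 ** rng.uniform(np.log10(300), np.log10(5000))))
        orf_codons = max(30, int(0.6 * total) // 3)
        orf = "ATG" + "".join(rng.choice(_BIASED_CODONS, size=orf_codons - 2)) \
              + _STOPS[int(rng.integers(3))]
        utr_total = max(0, total - len(orf))
        utr5 = _random_seq(rng, utr_total // 2)
        utr3 = _random_seq(rng, utr_total - utr_total // 2)
        seq = utr5 + orf + utr3
        tx = f"coding_{i + 1:04d}"
        seqs[tx] = seq
        labels[tx] = "coding"
        place(tx, len(seq), i, "coding")

    for i in range(n_noncoding):
        total = int(round(10 ** rng.uniform(2.0, np.log10(5000))))  # from 100 nt
        p = rng.dirichlet([6, 4, 4, 6])  # skewed, AT-leaning composition
        seq = _random_seq(rng, total, p=p)
        if total >= 300:
            seq = _kill_long_orfs(seq, rng)
        tx = f"noncoding_{i + 1:04d}"
        seqs[tx] = seq
        labels[tx] = "noncoding"
        place(tx, len(seq), n_coding + i, "linc")

    annotation = GeneAnnotationTable(pd.DataFrame(rows))
    return seqs, annotation, labels


def simulate_linc_candidates(
    config: SimConfig,
    n_samples: int = 12,
    n_known_fraction: float = 0.696,
    both_batch_prob: float = 0.75,
    expressed_prob: float = 0.85,
    coding_contamination: int = 60,
) -> tuple[list, list[GeneAnnotationTable], dict]:
    """Candidate transcripts for the lincRNA curation chain, with truth.

    Noncoding transcripts from the catalog (plus a coding contamination)
    become candidates carrying batch ids and per-sample FPKM.  A fraction
    of the noncoding loci is copied into a synthetic "known" annotation
    catalog, so curation survivors split into known and novel classes
    (the known fraction default mirrors a roughly 70/30 split).  Returns
    (candidates, known annotation catalogs, truth) where truth maps each
    candidate id to its expected fate.
    """
    from .lincfilter import TranscriptCandidate

    seqs, annotation, labels = simulate_transcript_catalog(config)
    rng = np.random.default_rng((config.seed + 15486041) % 2**31)
    ann = annotation.table.set_index("gene_id")
    noncoding_ids = [i for i in sorted(seqs) if labels[i] == "noncoding"]
    coding_ids = [i for i in sorted(seqs) if labels[i] == "coding"]
    chosen = noncoding_ids + list(rng.choice(coding_ids, size=min(
        coding_contamination, len(coding_ids)), replace=False))

    sample_ids = [f"N{i + 1:02d}" for i in range(n_samples)]
    candidates = []
    truth: dict[str, dict] = {}
    known_rows = []
    for tx in chosen:
        row = ann.loc[tx]
        expressed = bool(rng.random() < expressed_prob)
        if expressed:
            vals = rng.lognormal(np.log(8.0), 0.4, size=n_samples)
        else:
            vals = rng.lognormal(np.log(1.0), 0.4, size=n_samples)
        fpkm = pd.Series(vals, index=sample_ids)
        both = bool(rng.random() < both_batch_prob)
        batches = ["batch1", "batch2"] if both else [f"batch{rng.integers(1, 3)}"]
        for b in batches:
            candidates.append(TranscriptCandidate(
                id=f"{tx}.{b}", chrom=row["chrom"], start=row["start"],
                end=row["end"], strand=row["strand"],
                exons=tuple(row["exons"]), sequence=seqs[tx],
                batch=b, fpkm=fpkm))
        known = bool(labels[tx] == "noncoding" and rng.random() < n_known_fraction)
        if known:
            known_rows.append({
                "gene_id": f"known_{tx}", "chrom": row["chrom"],
                "start": row["start"], "end": row["end"],
                "strand": row["strand"], "biotype": "linc",
                "exons": list(row["exons"]),
                "length": int(row["length"]),
            })
        truth[tx] = {
            "label": labels[tx],
            "length": int(row["length"]),
            "expressed": expressed,
            "both_batches": both,
            "known": known,
        }
    known_catalog = GeneAnnotationTable(pd.DataFrame(known_rows)) if known_rows else None
    catalogs = [known_catalog] if known_catalog is not None else []
    return candidates, catalogs, truth
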