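# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `snucseq`, stage by stage.

## The synthetic experiment

The generator (`snucseq.simulate`) is first-class, tested code: it defines
the study conditions under which every downstream claim is verified, so
its design is the most consequential part of the package.

**Count model.** Each gene × nucleus observation is a negative-binomial
draw around a designed per-nucleus mean FPKM (variance μ + d·μ², default
dispersion d = 0.3), thinned by a Bernoulli dropout whose probability is
logistic in the log of the gene's typical abundance in that nucleus's
subgroup: p_drop = 1 / (1 + (m/m₀)^s) with midpoint m₀ = 2.5 FPKM and
steepness s = 2.5. The steep curve means genes above ~10 FPKM are detected
essentially always while genes below ~1 FPKM are mostly absent, so
penetrance rises sharply with abundance. Dropout keys on the subgroup-level
mean (detectability), not the activity-jittered instantaneous mean —
otherwise strong per-nucleus activity swings would punch spurious zeros
into highly expressed co-regulated genes. Library sizes are log-normal
around 8.5 M with σ = 0.35.

**FPKM is compositional.** For emitted data, FPKM is recomputed from the
realised counts, gene lengths (uniform 0.5–5 kb) and per-nucleus totals, so
the FPKM identity holds to numerical precision. A consequence worth
spelling out: the realised FPKM of every gene equals its designed value
times 10⁶ / (surviving designed mass in FPKM·kb), *independent of any
rescaling of the designed profile*. Absolute thresholds (the FPKM ≥ 4 gate,
the quadrant threshold) therefore only mean what they say if the designed
transcriptome's surviving mass is ~10⁶. The six core genes serve as the
free mass reservoir: their level is assigned adaptively so the mean
nucleus's surviving mass is exactly 10⁶, which lands them at ~20–50 k FPKM
— the most abundant genes in every nucleus, as constitutive sarcomere
transcripts are in real cardiomyocyte data — and pins every other gene's
realised FPKM to its designed value within a few percent.

**Subgroup structure.** Background "heterogeneity" genes (85% of the
background; ~680 genes at default size) toggle between an off state near
the detection floor (base ≈ 1.4 FPKM) and an on state 5.5–8.5 log2 units
higher, independently per subgroup. This bounded presence/absence
heterogeneity dominates the shared mean profile in pairwise log-space
correlations, producing exactly four dendrogram branches at the analysis
cut height of 0.75 (within-subgroup r ≈ 0.8, between ≈ 0.15–0.2). Two
condition-level asymmetries create the disease contrast: TAC nuclei turn
on more heterogeneity genes (on-probability 0.58 vs 0.42), so more genes
pass the expression gate in TAC; and the second TAC subgroup copies the
first subgroup's state for 15% of genes (the partly shared stress
response), so pairwise correlations among TAC nuclei are stochastically
larger than among Sham nuclei. A `condition_share` of ~0.35 makes even the
median TAC pair correlation exceed Sham's; the default keeps the contrast
detectable by the Mann–Whitney density test while preserving all four
branches.

**Modules and hubs.** Three planted modules of 50 genes (baseline ≈ 20
FPKM) are activated 4-fold in one subgroup each (healthy → Sham A,
disease 1 → TAC A, disease 2 → TAC B) and co-fluctuate in *every* nucleus
through a per-nucleus latent activity (σ = 2.0 log2) scaled by per-gene
loadings (uniform 0.6–0.88). The hub of each module has loading 1.0, low
intrinsic dispersion (0.05) and high abundance (100 FPKM baseline), making
it the member that tracks the module activity most faithfully — the
synthetic analogue of a nodal regulator. Heterogeneity genes never carry a
single-subgroup on/off pattern; that signature is reserved for the
modules, which would otherwise be statistically indistinguishable from
same-pattern background (correlation is scale-invariant).

**Panels, DE genes, lincRNAs.** Two 8-gene marker panels are jointly
switched on (8 FPKM vs 0.2) in 60% of TAC-A nuclei and nowhere else; the
co-activating nuclei are the quadrant-analysis ground truth. A dedicated
set of 60 DE genes carries a clean 4-fold (log2 = 2) difference between
the two TAC subgroups against ordinary NB noise — the planted effect for
power/false-positive evaluation (module genes also differ 4-fold, but
their latent activity is genuine within-group biological variance and
makes them a deliberately harder target). Sixty lincRNA genes have a wide
abundance spread (log-normal around 40 FPKM); in matched bulk profiles,
non-linc genes are amplified by the `nuclear_retention_factor` (default
10×, the cytoplasmic mRNA pool) before library renormalization, so the
lower half of the linc distribution falls below the gate in bulk
(~40–55% "nuclear-only") while passing in nuclei. Bulk mixtures add
deterministic background cell-type signatures (fibroblast, endothelial)
with their own marker genes.

**Transcript catalog.** Coding transcripts carry a planted ORF (~60% of
the transcript, biased codon usage); noncoding transcripts have skewed
per-transcript base composition and any chance ORF longer than 240 nt is
disrupted. Lengths are log-uniform over 100–5000 nt so the 200 bp filter
is exercised. The candidate builder attaches batch ids (75% discovered in
both batches), per-sample FPKM (85% expressed), and copies 70% of the
noncoding loci into a synthetic "known" catalog, so curation survivors
split roughly 70/30 into known/novel.

**Determinism.** All randomness flows from one `numpy.random.Generator`
per call; identical (config, seed) gives byte-identical outputs.

**What the generator does not emulate.** No read-level simulation, UMIs,
ambient RNA, doublets, batch effects on expression levels, gene-length
biases in dropout, or isoform structure. The heterogeneity model is
binary on/off rather than a continuum, and module activity is a single
latent factor. Passing recovery tests on these data shows that the
implementations detect the structures they target at realistic effect
sizes and noise levels; it does not certify performance on real tissue.

## Analysis stages

**Gating, ranks, core genes.** The gate keeps genes with FPKM ≥ 4 in ≥ 5
samples (both boundaries inclusive) and is monotone in both thresholds.
Per-sample ranks are descending-FPKM competition ranks (ties take the
minimum rank, so a "top R" cut is conservative). Core genes require FPKM
≥ 4 *and* rank ≤ R in every group sample. The classical R = 500 was set
against a ~20k-gene transcriptome; the pipeline scales it to 2.5% of the
gene universe (30 of 1200) so the cut has the same selectivity. CoV uses
the population SD (n denominator, configurable) and is flagged undefined
at zero mean. Penetrance uses the same FPKM ≥ 4 notion as the gate.

**Heterogeneity.** Sample correlations are Pearson on log2(FPKM+1) over
gated genes; zero-variance samples are excluded with a warning. Subgroups
are flat clusters of the average-linkage tree on 1 − r at cut height 0.75;
labels are named by majority condition plus a letter. The sample-tree
linkage is not uniquely determined by convention; average linkage was
chosen (matching the network stage) and is configurable. The correlation
density comparison is a two-sided Mann–Whitney U: exact enumeration over
all C(n+m, n) group assignments (midranks for ties, two-sided p = twice
the smaller tail, capped at 1) when both groups have ≤ 8 values, else the
normal approximation with tie and continuity correction. PCA standardizes
each gene to zero mean and unit variance, drops constant genes, and
orients each PC so its largest-magnitude loading is positive.

**Pooling.** Read subsampling is modelled at the gene-count level as a
multivariate hypergeometric draw (without replacement, so a full-depth
draw returns the original counts and every draw sums exactly to the
requested depth); beyond numpy's exact-sampler limit (totals ≥ 1e9) a
multinomial approximation is used, indistinguishable when the subsample is
a small fraction of the total. Pools aggregate all single nuclei of a
condition and are subsampled at a fixed depth; FPKM is recomputed per
pool. Correlation saturation draws random sample subsets of prescribed
sizes (default 2–35, 10 replicates) and correlates the subset-mean profile
with a reference on log2(FPKM+1).

**Network.** Adjacency, TOM, eigengenes, kME, pruning, disbanding and
merging follow the signed weighted-correlation-network recipe with the
formulas in the README; β defaults to 6, with the alternative power 3
available (the source protocol records both and does not disambiguate).
The scale-free fit index bins connectivities into 10 equal-width bins and
returns the slope-signed R² of log10 frequency on log10 mean-k. Module
detection is a simplified dynamic branch cut, top-down on the
average-linkage tree of 1 − TOM: a branch becomes a module when it is no
larger than `max_module_size` (80), *coherent* — its merge height within
`split_gap` (0.08) of the median height at which its members joined, which
rejects chains of late, loosely attached outsiders — and strictly
separated from its parent merge; otherwise it is split, and fragments
below `min_module_size` (15) stay unassigned. This replaces the published
dynamic hybrid algorithm; the planted-module recovery rate is the
acceptance surface for the simplification. Pruning iterates to a fixed
point (≤ 10 rounds): members with kME < 0.3 are dropped and modules
lacking 5 members at kME ≥ 0.5 are disbanded; merging greedily joins the
most-correlated eigengene pair while the correlation exceeds 0.75
(exactly 0.75 does not merge). Eigengenes are the first right singular
vector of the standardized member matrix, oriented to correlate
positively with the module's mean standardized profile. Module–trait
p-values use the two-sided t approximation of the correlation test, with
no multiplicity correction (raw associations are reported, as in standard
network practice).

**Quadrant analysis.** The per-sample axis summary is the arithmetic mean
FPKM over panel members (median and max available); a value exactly at the
threshold counts as high, consistent with the ≥ gate. The shift test
builds the 2 × 2 table condition × (focal quadrant vs not) and applies the
from-scratch Fisher exact test (two-sided by summing hypergeometric
probabilities ≤ the observed table's, with 1e-7 relative slack; any zero
margin gives p = 1); a 2 × 4 chi-square alternative is provided. The DE
test is the classic conditional NB exact test: median-of-ratios size
factors (best estimated on the full count matrix and passed in when
testing a gene subset), per-gene method-of-moments dispersion pooled
across groups (floored at 1e-8; the reference tool's cross-gene dispersion
sharing is deliberately simplified to keep the estimator oracle-checkable),
group totals moment-matched to NB distributions, and a two-sided p summing
the probabilities of splits no more likely than the observed one. The
enumeration is windowed to ±12 SD of the conditional support (excluded
tail mass < 1e-20). In the dispersion → 0, equal-size-factor limit the
test converges to the binomial exact test. BH adjustment is the
statsmodels step-up.

**lincRNA curation.** The four coding-potential features are the longest
ATG→stop ORF over the three sense-strand frames (Ns break ORFs; size
includes the stop codon), ORF coverage, the Fickett TESTCODE statistic
computed from the classical position/content lookup tables bundled as
module constants, and the mean in-frame log hexamer frequency ratio
against pseudocounted tables trained from labelled sequences. The logistic
classifier standardizes the four features; published organism-specific
weights are not bundled — the classifier is trained on labelled (synthetic
or user) transcripts, and the decision rule is "coding iff probability
> 0.44". The curation chain applies, in order: coding probability ≤ 0.44;
length ≥ 200 nt; FPKM ≥ 4 in ≥ 5 samples; identical exon chain discovered
in more than one batch (deduplicated to one representative; a ±10 nt
single-exon near-match is available via the candidate equality you choose
to construct). Novelty is ≥ 1 bp same-strand exonic overlap with any
reference exon (interval trees); the overlap rule is a package convention
since none is universally fixed. Detectability classes apply the
expression gate separately per assay. Neighbor correlation uses Spearman
per linc–gene pair, the span gap as distance, and a bootstrap 95% interval
per distance bin.

## Problem sizes and tolerances

The default synthetic experiment is 1200 genes × 80 nuclei (4 subgroups
× 20), a deliberate desk-scale surrogate for a transcriptome; rank-based
cuts are scaled to the universe (see core genes). The test suite's
Monte-Carlo properties run 100 seeds at these sizes; the acceptance
script's summaries use 50 seeds (25 for the exact-test power loop) —
enough for percentages stable to a few points. Numerical tolerances:
TOM and adjacency are locked to brute-force oracles at 1e-10/1e-12; the
Fisher test to exhaustive enumeration at 1e-9 relative; the exact-path
Mann–Whitney to assignment enumeration at 1e-9; the DE binomial limit to
1e-3 absolute. Degenerate inputs (constant genes or samples, zero counts,
zero margins, empty modules) are either excluded with a warning or
rejected with a named error rather than repaired.

## Known limitations

The module detector's coherence cut is a heuristic replacement for the
published dynamic hybrid tree cut and can shave a few late-joining module
members on noisy draws (recovery is ~97/100 seeds at ARI ≥ 0.9, not 100).
The DE dispersion estimator does not share information across genes, so
power on genes with strong latent co-fluctuation (the module members) is
lower than a shrinkage estimator would give. The Fickett tables are the
classical published constants; no attempt is made to re-derive them. The
generator's FPKM self-consistency holds in the mean nucleus; individual
nuclei deviate by a few percent with the realised mass, which is why
threshold margins in the planted structure are kept ≳ 25%.
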