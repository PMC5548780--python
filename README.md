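# snucseq

Single-nucleus cardiomyocyte transcriptome analysis: a tested, reusable
implementation of the analysis chain used to dissect expression
heterogeneity in failing (TAC, transverse aortic constriction) versus
non-failing (Sham) mouse hearts from single-nucleus RNA-seq FPKM matrices.

The package is aimed at computational biologists who want to run — or
stress-test on data with known ground truth — the following stages:

* **Expression gating and core genes** (`snucseq.exprstats`): a gene is
  expressed when FPKM ≥ 4 in at least 5 samples; *core genes* are expressed
  at FPKM ≥ 4 **and** ranked in the top *R* by FPKM in every nucleus of a
  reference group, with low coefficient of variation (CoV = σ/μ);
  *penetrance* (the percentage of samples expressing a gene) rises with
  mean expression.
* **Heterogeneity** (`snucseq.heterogeneity`): Pearson correlation between
  nuclei on log2(FPKM+1), average-linkage clustering on distance 1 − r cut
  at height 0.75 (yielding the Sham A/B and TAC A/B subgroups), PCA on
  gene-standardized FPKM, and a two-sided Mann–Whitney U comparison of the
  condition-wise correlation densities (exact enumeration at small n).
* **In-silico pooling and saturation** (`snucseq.pooling`): count-level
  read subsampling (multivariate hypergeometric), aggregation of all
  nuclei of a condition into depth-matched pools, and correlation
  saturation over growing sample subsets — the analyses that show how
  pooling masks single-nucleus signal.
* **Signed weighted co-expression network** (`snucseq.coexnet`), written
  from scratch: adjacency a_ij = (0.5 + 0.5·s_ij)^β (default β = 6),
  scale-free fit index, signed topological overlap
  TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij),
  average-linkage module detection with a simplified dynamic branch cut,
  module eigengenes (first PC), kME pruning (< 0.3 dropped; modules
  lacking 5 members at kME ≥ 0.5 disbanded), eigengene merging
  (correlation > 0.75), gene significance / module membership trait
  association, and a graph-viewer export.
* **Quadrant co-expression analysis** (`snucseq.quadrant`): each nucleus
  is classified by the mean FPKM of two marker panels against a threshold
  of 4 into Q1–Q4 (Q2 = co-expressing both); condition shifts into a
  focal quadrant are tested with a from-scratch two-sided Fisher exact
  test, and between-group differential expression uses a DESeq-style
  conditional negative-binomial exact test with median-of-ratios size
  factors and Benjamini–Hochberg adjustment.
* **Nuclear lincRNA curation** (`snucseq.lincfilter`): longest-ORF size
  and coverage, the classical Fickett TESTCODE statistic, hexamer usage
  bias, a logistic coding-potential classifier (coding iff probability
  > 0.44), strand-aware exonic novelty calls against reference catalogs,
  the sequential curation chain (noncoding → ≥ 200 nt → expressed →
  discovered in both batches), nuclear-vs-bulk detectability, and
  neighbor-correlation-vs-distance profiles.
* **Synthetic data with ground truth** (`snucseq.simulate`): a
  negative-binomial + dropout generator that plants the full study
  structure — four nuclear subgroups, a partly shared TAC stress response,
  three co-expression modules with hub genes, panel co-activation confined
  to one TAC subgroup, 4-fold differential genes, nuclear-retained
  lincRNAs, and a coding/noncoding transcript catalog.

`snucseq.io` provides the validated containers and TSV/MTX/GTF/BED/FASTA
readers and writers; `snucseq.pipeline` orchestrates everything from one
config into a manifest and report.

## Worked example

```python
from snucseq.pipeline import run_pipeline, write_report
from snucseq.simulate import SimConfig

manifest = run_pipeline(SimConfig(seed=3))
print(write_report(manifest, "report.txt"))
```

Selected lines of the report this prints (seed 3, default configuration —
1200 genes, 4 × 20 nuclei):

```
[exprstats]
  expressed_Sham: 965
  expressed_TAC: 1049
  core_gene_count: 6
  penetrance_rho: 0.9938
[heterogeneity]
  n_subgroups: 4
  subgroup_ari: 1
  corr_test_p: 1.395e-09
[coexnet]
  n_modules: 14
  module_ari: 0.99
[quadrant]
  q2_fraction: {'Sham': 0.0, 'TAC': 0.3}
  fisher_p: 0.0001855
[lincfilter]
  nuclear_only_fraction: 0.4667
  novel_fraction: 73/267 (27.3%)
```

Reading it: more genes pass the expression gate in the failing (TAC)
hearts than in Sham; the six planted core genes are recovered exactly and
penetrance tracks abundance (Spearman ρ ≈ 0.99 among detection-governed
genes); the nuclei split into exactly the four planted subgroups
(adjusted Rand index 1.0) and the TAC correlation density differs from
Sham's (Mann–Whitney p ≈ 1e-9); the network recovers the planted modules
(ARI 0.99 over planted genes); 30% of TAC nuclei co-express both marker
panels (none in Sham, Fisher p ≈ 2e-4); and about half of the planted
nuclear lincRNAs are detectable only in nuclei, with ~27% of curated
lincRNAs absent from the reference catalogs.

The same stages are scriptable from the shell:

```bash
snucseq simulate --seed 1 --out matrix.tsv --samples-out samples.tsv
snucseq gate matrix.tsv
snucseq cluster matrix.tsv --cut-height 0.75
snucseq pipeline --seed 1 --report report.txt
```

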