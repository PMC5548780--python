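"""Nuclear lincRNA curation: coding potential, novelty, and filter chain.

Candidate transcripts are scored with four classical coding-potential
features — longest ORF size, ORF coverage, the Fickett TESTCODE statistic
and hexamer usage bias — combined by a logistic regression into a coding
probability.  A transcript with probability strictly above 0.44 is called
coding.  The curation chain then keeps noncoding candidates of at least
200 nt, expressed at FPKM >= 4 in at least 5 samples, and discovered in
both sequencing batches (exact exon-chain match), annotating each survivor
as novel or known by strand-aware exonic overlap with reference catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix, GeneAnnotationTable

__all__ = [
    "TranscriptCandidate",
    "CodingFeatures",
    "longest_orf",
    "fickett_testcode",
    "hexamer_tables",
    "hexamer_bias",
    "featurize",
    "CodingClassifier",
    "novelty_overlap",
    "curate_lincms",
    "nuclear_vs_bulk_detectability",
    "neighbor_correlation_vs_distance",
    "CODING_CUTOFF",
]

CODING_CUTOFF = 0.44
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class TranscriptCandidate:
    """A candidate transcript with locus, sequence and discovery batch."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str
    batch: str | None = None
    fpkm: pd.Series | None = None

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        spliced = sum(e - s for s, e in self.exons)
        if self.sequence and len(self.sequence) != spliced:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != spliced length {spliced}")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_chain(self) -> tuple:
        return (self.chrom, self.strand, self.exons)


@dataclass(frozen=True)
class CodingFeatures:
    """The four coding-potential features and the resulting probability."""

    orf_size: int
    orf_coverage: float
    fickett: float
    hexamer: float
    coding_prob: float | None = None


# ---------------------------------------------------------------------------
# ORF


def longest_orf(sequence: str, return_start: bool = False):
    """Longest ATG->stop ORF over the three sense-strand frames.

    Returns (orf_size_nt, orf_coverage); with ``return_start`` also the
    0-based start position.  Ns break ORFs (codons containing N neither
    start nor extend one).  The size includes the stop codon.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    best_size = 0
    best_start = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" in codon:
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                size = pos + 3 - start
                if size > best_size:
                    best_size, best_start = size, start
                start = None
    coverage = best_size / n
    if return_start:
        return best_size, coverage, best_start
    return best_size, coverage


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# The classical TESTCODE lookup tables: for each base, a position parameter
# (max/min asymmetry of the base count across the three codon positions)
# and a content parameter (base fraction), each mapped through a probability
# table and weighted by the parameter's historical discriminative power.

_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: Sequence[float], prob: Sequence[float]) -> float:
    for idx, threshold in enumerate(para):
        if value >= threshold:
            return prob[idx]
    return prob[-1]


def fickett_testcode(sequence: str) -> float:
    """Fickett TESTCODE statistic from base position/content lookup tables.

    Requires at least 12 nt (three observations per codon position);
    shorter input returns NaN.  Case-insensitive; non-ACGT symbols are
    ignored for content and position counts.
    """
    seq = sequence.upper()
    if len(seq) < 12:
        return float("nan")
    score = 0.0
    total = sum(seq.count(b) for b in _BASES)
    if total == 0:
        return float("nan")
    for base in _BASES:
        counts = [seq[frame::3].count(base) for frame in range(3)]
        position_value = max(counts) / (min(counts) + 1.0)
        score += _lookup(position_value, _POSITION_PARA,
                         _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content_value = seq.count(base) / total
        score += _lookup(content_value, _CONTENT_PARA,
                         _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# hexamer usage bias


def _all_hexamers() -> list[str]:
    from itertools import product

    return ["".join(p) for p in product(_BASES, repeat=6)]


def hexamer_tables(
    coding_seqs: Iterable[str],
    noncoding_seqs: Iterable[str],
    pseudocount: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """In-frame hexamer frequency tables from labelled training sequences.

    Coding sequences are counted in their longest-ORF frame; noncoding in
    frame 0.  Both tables are pseudocounted over all 4096 hexamers.
    """
    hexamers = _all_hexamers()

    def count(seqs: Iterable[str], use_orf_frame: bool) -> pd.Series:
        counts = dict.fromkeys(hexamers, pseudocount)
        for seq in seqs:
            seq = seq.upper()
            frame = 0
            if use_orf_frame:
                size, _cov, start = longest_orf(seq, return_start=True)
                frame = start % 3 if size > 0 else 0
            for pos in range(frame, len(seq) - 5, 3):
                h = seq[pos:pos + 6]
                if h in counts:
                    counts[h] += 1
        s = pd.Series(counts)
        return s / s.sum()

    return count(coding_seqs, True), count(noncoding_seqs, False)


def hexamer_bias(sequence: str, coding_freq: pd.Series, noncoding_freq: pd.Series) -> float:
    """Mean log(coding/noncoding) frequency ratio over in-frame hexamers.

    The frame is the longest-ORF frame, or frame 0 when no ORF exists.
    Sequences shorter than 6 nt return NaN.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        return float("nan")
    size, _cov, start = longest_orf(seq, return_start=True)
    frame = start % 3 if size > 0 else 0
    ratios = []
    for pos in range(frame, len(seq) - 5, 3):
        h = seq[pos:pos + 6]
        if h in coding_freq.index and h in noncoding_freq.index:
            ratios.append(np.log(coding_freq[h] / noncoding_freq[h]))
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# classifier


def featurize(sequence: str, coding_freq: pd.Series, noncoding_freq: pd.Series) -> CodingFeatures:
    size, cov = longest_orf(sequence)
    return CodingFeatures(
        orf_size=size,
        orf_coverage=cov,
        fickett=fickett_testcode(sequence),
        hexamer=hexamer_bias(sequence, coding_freq, noncoding_freq),
    )


_FEATURE_COLS = ("orf_size", "orf_coverage", "fickett", "hexamer")


class CodingClassifier:
    """Logistic regression on the four standardized coding-potential features.

    Either fit on a labelled training set (both classes required) or built
    from explicit ``weights`` (intercept + 4 coefficients on raw features).
    Probability strictly above the cutoff (default 0.44) is called coding.
    """

    def __init__(self, cutoff: float = CODING_CUTOFF,
                 weights: Sequence[float] | None = None) -> None:
        self.cutoff = cutoff
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self._scaler: StandardScaler | None = None
        self._model: LogisticRegression | None = None
        if self.weights is not None and len(self.weights) != 5:
            raise ValueError("weights must be (intercept, 4 coefficients)")

    @staticmethod
    def _matrix(features: Sequence[CodingFeatures]) -> np.ndarray:
        x = np.array([[getattr(f, c) for c in _FEATURE_COLS] for f in features],
                     dtype=float)
        return np.nan_to_num(x, nan=0.0)

    def fit(self, features: Sequence[CodingFeatures], labels: Sequence[str]) -> "CodingClassifier":
        y = np.array([1 if l == "coding" else 0 for l in labels])
        if len(set(y)) < 2:
            raise ValueError("training set must contain both classes")
        x = self._matrix(features)
        self._scaler = StandardScaler().fit(x)
        self._model = LogisticRegression(max_iter=1000).fit(
            self._scaler.transform(x), y)
        return self

    def predict_proba(self, features: Sequence[CodingFeatures]) -> np.ndarray:
        x = self._matrix(features)
        if self.weights is not None:
            z = self.weights[0] + x @ self.weights[1:]
            return 1.0 / (1.0 + np.exp(-z))
        if self._model is None:
            raise ValueError("classifier is neither fitted nor given weights")
        return self._model.predict_proba(self._scaler.transform(x))[:, 1]

    def classify(self, prob: float | np.ndarray) -> np.ndarray:
        """'coding' iff probability > cutoff (0.44 exactly is noncoding)."""
        prob = np.asarray(prob)
        return np.where(prob > self.cutoff, "coding", "noncoding")


# ---------------------------------------------------------------------------
# novelty


def _exon_trees(annotations: Sequence[GeneAnnotationTable]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for ann in annotations:
        for row in ann.table.itertuples(index=False):
            key = (row.chrom, row.strand)
            tree = trees.setdefault(key, IntervalTree())
            for s, e in row.exons:
                tree[s:e] = row.gene_id
    return trees


def novelty_overlap(
    candidates: Sequence[TranscriptCandidate],
    known_annotations: Sequence[GeneAnnotationTable],
) -> pd.Series:
    """'known' iff >= 1 bp exonic overlap with any known transcript's exon
    on the same strand; else 'novel'."""
    trees = _exon_trees(known_annotations)
    calls = {}
    for c in candidates:
        tree = trees.get((c.chrom, c.strand))
        hit = bool(tree) and any(tree.overlap(s, e) for s, e in c.exons)
        calls[c.id] = "known" if hit else "novel"
    return pd.Series(calls, name="novelty")


# ---------------------------------------------------------------------------
# curation chain


def curate_lincms(
    candidates: Sequence[TranscriptCandidate],
    matrix: ExpressionMatrix | None,
    known_annotations: Sequence[GeneAnnotationTable],
    classifier: CodingClassifier,
    coding_freq: pd.Series,
    noncoding_freq: pd.Series,
    min_length: int = 200,
    fpkm_min: float = 4.0,
    min_samples: int = 5,
    require_both_batches: bool = True,
) -> tuple[list[TranscriptCandidate], pd.Series, pd.DataFrame]:
    """Sequential lincRNA curation with per-step survivor counts.

    Steps: (1) coding probability <= cutoff, (2) length >= ``min_length``,
    (3) FPKM >= ``fpkm_min`` in >= ``min_samples`` samples, (4) identical
    exon chain discovered in more than one batch (deduplicated to one
    representative).  Returns survivors, their novel/known calls, and the
    provenance table.
    """
    surviving = list(candidates)
    steps = [("input", len(surviving))]

    feats = [featurize(c.sequence, coding_freq, noncoding_freq) for c in surviving]
    probs = classifier.predict_proba(feats)
    surviving = [c for c, p in zip(surviving, probs) if p <= classifier.cutoff]
    steps.append(("noncoding", len(surviving)))

    surviving = [c for c in surviving if c.length >= min_length]
    steps.append(("length", len(surviving)))

    def expressed(c: TranscriptCandidate) -> bool:
        if c.fpkm is not None:
            vals = c.fpkm.to_numpy()
        elif matrix is not None and c.id in matrix.fpkm.index:
            vals = matrix.fpkm.loc[c.id].to_numpy()
        else:
            return False
        return int((vals >= fpkm_min).sum()) >= min_samples

    surviving = [c for c in surviving if expressed(c)]
    steps.append(("expression", len(surviving)))

    if require_both_batches:
        for c in surviving:
            if c.batch is None:
                raise ValueError(f"candidate {c.id} has no batch id")
        by_chain: dict[tuple, list[TranscriptCandidate]] = {}
        for c in surviving:
            by_chain.setdefault(c.exon_chain, []).append(c)
        surviving = [
            min(group, key=lambda c: c.id)
            for group in by_chain.values()
            if len({c.batch for c in group}) >= 2
        ]
        surviving.sort(key=lambda c: c.id)
    steps.append(("both_batches", len(surviving)))

    novelty = novelty_overlap(surviving, known_annotations)
    provenance = pd.DataFrame(steps, columns=["step", "surviving"])
    return surviving, novelty, provenance


# ---------------------------------------------------------------------------
# nuclear vs bulk detectability


def nuclear_vs_bulk_detectability(
    genes: Sequence[str],
    nuclear: ExpressionMatrix,
    bulk: ExpressionMatrix,
    fpkm_min: float = 4.0,
    min_samples: int = 5,
) -> pd.Series:
    """Classify genes as both / nuclear_only / bulk_only / neither by the
    expression gate applied separately in each assay."""
    from .exprstats import gate_expressed

    nuc_set, _ = gate_expressed(nuclear, fpkm_min, min(min_samples, nuclear.n_samples))
    bulk_set, _ = gate_expressed(bulk, fpkm_min, min(min_samples, bulk.n_samples))
    calls = {}
    for g in genes:
        in_nuc, in_bulk = g in nuc_set, g in bulk_set
        calls[g] = ("both" if in_nuc and in_bulk else
                    "nuclear_only" if in_nuc else
                    "bulk_only" if in_bulk else "neither")
    return pd.Series(calls, name="detectability")


# ---------------------------------------------------------------------------
# neighbor correlation vs distance


def neighbor_correlation_vs_distance(
    linc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    linc_annotation: GeneAnnotationTable,
    gene_annotation: GeneAnnotationTable,
    distance_bins: Sequence[float] = (0, 1e4, 1e5, 1e6, 1e7),
    n_bootstrap: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of linc-neighbor expression, binned by distance.

    Distance is the gap between gene spans on the same chromosome (0 when
    overlapping).  Each bin reports the mean pair correlation with a 95%
    bootstrap interval.  Returns an empty table (with a warning) when no
    same-chromosome pair exists.
    """
    rng = np.random.default_rng(seed)
    linc_loci = linc_annotation.table.set_index("gene_id")
    gene_loci = gene_annotation.table.set_index("gene_id")
    shared = [s for s in linc_expr.columns if s in gene_expr.columns]
    pairs = []
    for linc in linc_expr.index:
        if linc not in linc_loci.index:
            continue
        lrow = linc_loci.loc[linc]
        for gene in gene_expr.index:
            if gene == linc or gene not in gene_loci.index:
                continue
            grow = gene_loci.loc[gene]
            if grow["chrom"] != lrow["chrom"]:
                continue
            gap = max(lrow["start"], grow["start"]) - min(lrow["end"], grow["end"])
            distance = max(0, gap)
            rho = stats.spearmanr(linc_expr.loc[linc, shared],
                                  gene_expr.loc[gene, shared]).statistic
            if np.isfinite(rho):
                pairs.append((distance, float(rho)))
    if not pairs:
        import warnings

        warnings.warn("no same-chromosome linc-gene pairs")
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_pairs",
                                     "mean_corr", "ci_low", "ci_high"])
    dist = np.array([p[0] for p in pairs])
    rho = np.array([p[1] for p in pairs])
    edges = np.asarray(distance_bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi) if hi < edges[-1] else (dist >= lo) & (dist <= hi)
        vals = rho[sel]
        if len(vals) == 0:
            continue
        boots = [np.mean(rng.choice(vals, size=len(vals), replace=True))
                 for _ in range(n_bootstrap)]
        rows.append({"bin_low": lo, "bin_high": hi, "n_pairs": int(sel.sum()),
                     "mean_corr": float(vals.mean()),
                     "ci_low": float(np.quantile(boots, 0.025)),
                     "ci_high": float(np.quantile(boots, 0.975))})
    return pd.DataFrame(rows)
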