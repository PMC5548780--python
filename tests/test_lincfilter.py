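"""Coding-potential features, classifier, novelty and the curation chain."""

import numpy as np
import pandas as pd
import pytest

from snucseq import lincfilter
from snucseq.io import ExpressionMatrix, GeneAnnotationTable
from snucseq.lincfilter import (CodingClassifier, TranscriptCandidate,
                                fickett_testcode, hexamer_bias, hexamer_tables,
                                longest_orf, novelty_overlap)


class TestLongestORF:
    def test_single_complete_orf(self):
        size, cov = longest_orf("ATGAAATAG")
        assert size == 9 and cov == 1.0

    def test_no_start_codon(self):
        size, cov = longest_orf("CCCCCCCCCCCC")
        assert size == 0 and cov == 0.0

    def test_longest_of_two_orfs(self):
        orf30 = "ATG" + "AAA" * 8 + "TAG"
        orf90 = "ATG" + "GAA" * 28 + "TGA"
        seq = orf30 + "CC" + orf90  # different frames
        size, _cov = longest_orf(seq)
        assert size == 90

    def test_n_breaks_orf(self):
        clean = "ATG" + "AAA" * 10 + "TAG"
        broken = "ATG" + "AAA" * 4 + "ANA" + "AAA" * 5 + "TAG"
        assert longest_orf(clean)[0] == 36
        assert longest_orf(broken)[0] < 36

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            longest_orf("")


class TestFickett:
    def test_pure_a_hand_walk(self):
        """120 A's: every position value = 40/41, every content = 1 or 0;
        walking the lookup tables by hand gives the exact score."""
        seq = "A" * 120
        # position parameter for every base: counts are (40,40,40) for A and
        # (0,0,0) otherwise -> value A = 40/41 < 1.1 -> last bin;
        # value C=G=T = 0/1 -> last bin
        # content A = 1.0 -> first bin (>= 0.33); C=G=T = 0 -> last bin
        expected = 0.0
        expected += lincfilter._POSITION_PROB["A"][-1] * lincfilter._POSITION_WEIGHT["A"]
        for b in "CGT":
            expected += lincfilter._POSITION_PROB[b][-1] * lincfilter._POSITION_WEIGHT[b]
        expected += lincfilter._CONTENT_PROB["A"][0] * lincfilter._CONTENT_WEIGHT["A"]
        for b in "CGT":
            expected += lincfilter._CONTENT_PROB[b][-1] * lincfilter._CONTENT_WEIGHT[b]
        assert fickett_testcode(seq) == pytest.approx(expected, abs=1e-12)

    def test_case_insensitive(self):
        seq = "atgGCCaaaTTTgggCCCtagACG" * 5
        assert fickett_testcode(seq) == fickett_testcode(seq.lower())

    def test_short_sequence_flagged(self):
        assert np.isnan(fickett_testcode("ACGTACGTACG"))  # 11 nt

    def test_codon_biased_scores_above_random(self):
        """Coding-style periodicity scores above uniform-random sequence."""
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        n = 300
        biased_scores, random_scores = [], []
        for _ in range(200):
            codons = rng.choice(["GAG", "AAG", "CTG", "GCC", "GAC"], size=n // 3)
            biased_scores.append(fickett_testcode("".join(codons)))
            random_scores.append(fickett_testcode("".join(rng.choice(bases, n))))
        assert np.mean(biased_scores) > np.mean(random_scores)


class TestHexamer:
    def test_identical_tables_score_zero(self):
        hexamers = lincfilter._all_hexamers()
        table = pd.Series(1.0 / len(hexamers), index=hexamers)
        assert hexamer_bias("ACGTACGTACGTACGTAC", table, table) == pytest.approx(0.0)

    def test_single_hexamer_ratio(self):
        hexamers = lincfilter._all_hexamers()
        cod = pd.Series(1.0, index=hexamers)
        non = pd.Series(1.0, index=hexamers)
        cod["AAAAAA"] = 2.0
        # sequence of one repeated hexamer with no ATG -> frame 0
        assert hexamer_bias("AAAAAA", cod, non) == pytest.approx(np.log(2.0))

    def test_18mer_hand_computation(self):
        hexamers = lincfilter._all_hexamers()
        cod = pd.Series(1.0, index=hexamers)
        non = pd.Series(1.0, index=hexamers)
        seq = "CCCGGGTTTAAACCGGTT"  # no ATG -> frame 0; hexamers at 0,3,6,9,12
        ratios = []
        for pos, ratio in [(0, 3.0), (3, 1.0), (6, 0.5), (9, 1.0), (12, 1.0)]:
            cod[seq[pos:pos + 6]] = ratio
            ratios.append(np.log(ratio / 1.0))
        expected = np.mean(ratios)
        assert hexamer_bias(seq, cod, non) == pytest.approx(expected, abs=1e-12)

    def test_short_sequence_flagged(self):
        hexamers = lincfilter._all_hexamers()
        t = pd.Series(1.0, index=hexamers)
        assert np.isnan(hexamer_bias("ACGTA", t, t))

    def test_trained_tables_separate_classes(self):
        from snucseq.simulate import SimConfig, simulate_transcript_catalog

        seqs, _ann, labels = simulate_transcript_catalog(
            SimConfig(seed=21), n_coding=60, n_noncoding=60)
        cod = [s for t, s in seqs.items() if labels[t] == "coding"]
        non = [s for t, s in seqs.items() if labels[t] == "noncoding"]
        cf, nf = hexamer_tables(cod[:40], non[:40])
        cod_scores = [hexamer_bias(s, cf, nf) for s in cod[40:]]
        non_scores = [hexamer_bias(s, cf, nf) for s in non[40:]]
        assert np.mean(cod_scores) > np.mean(non_scores)


class TestClassifier:
    def test_probability_exactly_cutoff_is_noncoding(self):
        clf = CodingClassifier(cutoff=0.44)
        assert clf.classify(0.44) == "noncoding"
        assert clf.classify(0.4400001) == "coding"

    def test_zero_weights_give_half_probability_coding(self):
        clf = CodingClassifier(weights=[0.0, 0, 0, 0, 0])
        feats = [lincfilter.CodingFeatures(100, 0.5, 0.8, 0.1)]
        prob = clf.predict_proba(feats)
        assert prob[0] == pytest.approx(0.5)
        assert clf.classify(prob)[0] == "coding"

    def test_single_class_training_rejected(self):
        feats = [lincfilter.CodingFeatures(10, 0.1, 0.5, 0.0)] * 4
        with pytest.raises(ValueError, match="both classes"):
            CodingClassifier().fit(feats, ["coding"] * 4)

    def test_heldout_auc_on_synthetic_transcripts(self):
        from sklearn.metrics import roc_auc_score

        from snucseq.simulate import SimConfig, simulate_transcript_catalog

        seqs, _ann, labels = simulate_transcript_catalog(
            SimConfig(seed=22), n_coding=150, n_noncoding=150)
        ids = sorted(seqs)
        rng = np.random.default_rng(1)
        train = set(rng.choice(ids, size=int(0.7 * len(ids)), replace=False))
        test = [i for i in ids if i not in train]
        cf, nf = hexamer_tables(
            [seqs[i] for i in sorted(train) if labels[i] == "coding"],
            [seqs[i] for i in sorted(train) if labels[i] == "noncoding"])
        clf = CodingClassifier().fit(
            [lincfilter.featurize(seqs[i], cf, nf) for i in sorted(train)],
            [labels[i] for i in sorted(train)])
        probs = clf.predict_proba(
            [lincfilter.featurize(seqs[i], cf, nf) for i in test])
        y = [1 if labels[i] == "coding" else 0 for i in test]
        assert roc_auc_score(y, probs) >= 0.95


def annotation(rows):
    return GeneAnnotationTable(pd.DataFrame(rows))


def candidate(id="c1", chrom="chr1", exons=((100, 200),), strand="+",
              seq=None, batch="batch1", fpkm=None):
    exons = tuple(exons)
    length = sum(e - s for s, e in exons)
    return TranscriptCandidate(
        id=id, chrom=chrom, start=exons[0][0], end=exons[-1][1], strand=strand,
        exons=exons, sequence=seq if seq is not None else "A" * length,
        batch=batch, fpkm=fpkm)


class TestNoveltyOverlap:
    def test_exonic_overlap_same_strand_is_known(self):
        known = annotation([{"gene_id": "k", "chrom": "chr1", "start": 150,
                             "end": 250, "strand": "+", "biotype": "linc",
                             "exons": [(150, 250)]}])
        calls = novelty_overlap([candidate(exons=[(100, 200)])], [known])
        assert calls["c1"] == "known"

    def test_opposite_strand_is_novel(self):
        known = annotation([{"gene_id": "k", "chrom": "chr1", "start": 100,
                             "end": 200, "strand": "-", "biotype": "linc",
                             "exons": [(100, 200)]}])
        calls = novelty_overlap([candidate(exons=[(100, 200)], strand="+")], [known])
        assert calls["c1"] == "novel"

    def test_intron_only_overlap_is_novel(self):
        known = annotation([{"gene_id": "k", "chrom": "chr1", "start": 0,
                             "end": 1000, "strand": "+", "biotype": "linc",
                             "exons": [(0, 100), (900, 1000)]}])
        calls = novelty_overlap([candidate(exons=[(400, 500)])], [known])
        assert calls["c1"] == "novel"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        known_rows = []
        for i in range(20):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(50, 400))
            known_rows.append({"gene_id": f"k{i}", "chrom": "chr1",
                               "start": start, "end": end,
                               "strand": rng.choice(["+", "-"]),
                               "biotype": "linc", "exons": [(start, end)]})
        known = annotation(known_rows)
        cands = []
        for i in range(50):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(50, 400))
            cands.append(candidate(id=f"c{i}", exons=[(start, end)],
                                   strand=rng.choice(["+", "-"])))
        calls = novelty_overlap(cands, [known])
        for c in cands:
            base_hit = any(
                r["strand"] == c.strand and
                max(r["start"], c.start) < min(r["end"], c.end)
                for r in known_rows)
            assert calls[c.id] == ("known" if base_hit else "novel")


class TestCurationChain:
    def _toy(self):
        """10 hand-designed candidates with known fates."""
        expressed = pd.Series([8.0] * 6 + [1.0] * 6)
        silent = pd.Series([3.999] * 12)
        coding_seq = "ATG" + "GAGAAGCTGGCCGAC" * 20 + "TAG"  # long ORF
        nc = None  # poly-A default sequence: no ORF, low coding potential
        cands = [
            candidate("t01", exons=[(0, 306)], seq=coding_seq, batch="batch1",
                      fpkm=expressed),                      # coding -> step 1
            candidate("t01b", exons=[(0, 306)], seq=coding_seq, batch="batch2",
                      fpkm=expressed),
            candidate("t02", exons=[(0, 199)], seq=nc, batch="batch1",
                      fpkm=expressed),                      # 199 nt -> step 2
            candidate("t03", exons=[(0, 300)], seq=nc, batch="batch1",
                      fpkm=silent),                         # FPKM 3.999 -> step 3
            candidate("t04", exons=[(0, 400)], seq=nc, batch="batch1",
                      fpkm=expressed),                      # batch1 only -> step 4
            candidate("t05", exons=[(1000, 1400)], seq=nc, batch="batch1",
                      fpkm=expressed),                      # survivor (novel)
            candidate("t05b", exons=[(1000, 1400)], seq=nc, batch="batch2",
                      fpkm=expressed),
            candidate("t06", exons=[(2000, 2200), (2300, 2500)], seq=nc,
                      batch="batch1", fpkm=expressed),      # survivor (known)
            candidate("t06b", exons=[(2000, 2200), (2300, 2500)], seq=nc,
                      batch="batch2", fpkm=expressed),
            candidate("t07", exons=[(5000, 5200)], seq=nc, batch="batch2",
                      fpkm=expressed),                      # batch2 only -> step 4
        ]
        known = annotation([{"gene_id": "k1", "chrom": "chr1", "start": 2100,
                             "end": 2150, "strand": "+", "biotype": "linc",
                             "exons": [(2100, 2150)]}])
        clf = CodingClassifier(weights=[-8.0, 0.02, 2.0, 2.0, 2.0])
        hexamers = lincfilter._all_hexamers()
        flat = pd.Series(1.0 / len(hexamers), index=hexamers)
        return cands, [known], clf, flat

    def test_hand_walked_filter_chain(self):
        cands, known, clf, flat = self._toy()
        survivors, novelty, prov = lincfilter.curate_lincms(
            cands, None, known, clf, flat, flat)
        assert [c.id for c in survivors] == ["t05", "t06"]
        assert novelty["t05"] == "novel"
        assert novelty["t06"] == "known"
        assert list(prov["surviving"]) == [10, 8, 7, 6, 2]

    def test_order_invariance(self):
        cands, known, clf, flat = self._toy()
        survivors1, _n1, _p1 = lincfilter.curate_lincms(
            cands, None, known, clf, flat, flat)
        survivors2, _n2, _p2 = lincfilter.curate_lincms(
            cands[::-1], None, known, clf, flat, flat)
        assert [c.id for c in survivors1] == [c.id for c in survivors2]

    def test_missing_batch_rejected(self):
        cands, known, clf, flat = self._toy()
        cands[5].batch = None
        with pytest.raises(ValueError, match="batch"):
            lincfilter.curate_lincms(cands, None, known, clf, flat, flat)


class TestDetectability:
    def _matrices(self):
        nuc = ExpressionMatrix(pd.DataFrame(
            {f"n{i}": [8.0, 1.0] for i in range(6)}, index=["linc1", "linc2"]))
        bulk = ExpressionMatrix(pd.DataFrame(
            {f"b{i}": [1.0, 1.0] for i in range(6)}, index=["linc1", "linc2"]))
        return nuc, bulk

    def test_nuclear_only_call(self):
        nuc, bulk = self._matrices()
        calls = lincfilter.nuclear_vs_bulk_detectability(
            ["linc1", "linc2"], nuc, bulk, min_samples=5)
        assert calls["linc1"] == "nuclear_only"
        assert calls["linc2"] == "neither"

    def test_identical_matrices_have_no_nuclear_only(self):
        nuc, _bulk = self._matrices()
        calls = lincfilter.nuclear_vs_bulk_detectability(
            ["linc1", "linc2"], nuc, nuc, min_samples=5)
        assert (calls != "nuclear_only").all()

    def test_simdata_nuclear_retention(self, default_sim):
        from snucseq.simulate import simulate_bulk

        m, _s, truth = default_sim
        bulk = simulate_bulk(truth, {"CM": 0.6, "fibroblast": 0.25,
                                     "endothelial": 0.15},
                             cytoplasmic_amplification=10.0)
        calls = lincfilter.nuclear_vs_bulk_detectability(
            list(truth.linc_genes), m, bulk)
        assert (calls == "nuclear_only").mean() >= 0.3


class TestNeighborCorrelation:
    def _annotations(self, loci):
        rows = [{"gene_id": g, "chrom": "chr1", "start": s, "end": e,
                 "strand": "+", "biotype": "linc", "exons": [(s, e)]}
                for g, s, e in loci]
        return annotation(rows)

    def test_duplicated_linc_at_distance_zero(self):
        rng = np.random.default_rng(30)
        expr = rng.uniform(0, 10, 20)
        linc_expr = pd.DataFrame([expr], index=["linc1"])
        gene_expr = pd.DataFrame([expr], index=["twin"])
        la = self._annotations([("linc1", 100, 200)])
        ga = self._annotations([("twin", 150, 250)])
        table = lincfilter.neighbor_correlation_vs_distance(
            linc_expr, gene_expr, la, ga, distance_bins=(0, 1000))
        assert table["mean_corr"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(31)
        n_genes, n_samples = 120, 30
        linc_expr = pd.DataFrame(rng.uniform(0, 10, (8, n_samples)),
                                 index=[f"l{i}" for i in range(8)])
        gene_expr = pd.DataFrame(rng.uniform(0, 10, (n_genes, n_samples)),
                                 index=[f"g{i}" for i in range(n_genes)])
        la = self._annotations([(f"l{i}", i * 10000, i * 10000 + 100)
                                for i in range(8)])
        ga = self._annotations([(f"g{i}", i * 800, i * 800 + 100)
                                for i in range(n_genes)])
        table = lincfilter.neighbor_correlation_vs_distance(
            linc_expr, gene_expr, la, ga, distance_bins=(0, 1e5), n_bootstrap=50)
        assert abs(table["mean_corr"].iloc[0]) < 0.05

    def test_planted_distance_trend_recovered(self):
        rng = np.random.default_rng(32)
        n_samples = 40
        base = rng.normal(0, 1, n_samples)
        linc_expr = pd.DataFrame([np.maximum(5 + base, 0)], index=["l0"])
        rows, loci = [], []
        for i in range(60):
            dist = (i + 1) * 5000
            weight = min(1.0, dist / 2e5)  # correlation grows with distance
            vals = 5 + weight * base + (1 - weight) * rng.normal(0, 1, n_samples)
            rows.append(np.maximum(vals, 0))
            loci.append((f"g{i}", 1000 + dist, 1100 + dist))
        gene_expr = pd.DataFrame(rows, index=[l[0] for l in loci])
        la = self._annotations([("l0", 0, 1000)])
        ga = self._annotations(loci)
        table = lincfilter.neighbor_correlation_vs_distance(
            linc_expr, gene_expr, la, ga,
            distance_bins=(0, 1e5, 2e5, 4e5), n_bootstrap=50)
        means = table["mean_corr"].to_numpy()
        assert (np.diff(means) > 0).all()

    def test_no_shared_chromosome_warns_empty(self):
        linc_expr = pd.DataFrame([[1.0, 2.0]], index=["l0"])
        gene_expr = pd.DataFrame([[1.0, 2.0]], index=["g0"])
        la = self._annotations([("l0", 0, 100)])
        ga = annotation([{"gene_id": "g0", "chrom": "chr9", "start": 0,
                          "end": 100, "strand": "+", "biotype": "other",
                          "exons": [(0, 100)]}])
        with pytest.warns(UserWarning, match="no same-chromosome"):
            table = lincfilter.neighbor_correlation_vs_distance(
                linc_expr, gene_expr, la, ga)
        assert table.empty
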