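"""Signed co-expression network: adjacency, TOM, modules, kME, traits."""

import numpy as np
import pandas as pd
import pytest

from snucseq import coexnet
from snucseq.io import ExpressionMatrix


def matrix_from_log2(genes):
    """FPKM matrix (genes as rows) whose log2(FPKM+1) values are given."""
    df = pd.DataFrame(genes).T
    return ExpressionMatrix(2.0 ** df - 1.0)


def planted_module_matrix(seed=0, sizes=(20, 20), n_noise=10, n_samples=30):
    rng = np.random.default_rng(seed)
    cols = {}
    latents = [rng.normal(0, 2, n_samples) for _ in sizes]
    gene = 0
    labels = {}
    for b, size in enumerate(sizes):
        for _ in range(size):
            vals = 5 + latents[b] + rng.normal(0, 0.4, n_samples)
            cols[f"g{gene}"] = np.maximum(vals, 0)
            labels[f"g{gene}"] = b
            gene += 1
    for _ in range(n_noise):
        cols[f"g{gene}"] = np.maximum(rng.normal(5, 2, n_samples), 0)
        labels[f"g{gene}"] = -1
        gene += 1
    return ExpressionMatrix(pd.DataFrame(cols).T), labels


class TestAdjacency:
    def test_formula_endpoints(self):
        x = np.linspace(0, 5, 10)
        m = matrix_from_log2({"a": x, "b": x, "c": 5 - x})
        net = coexnet.signed_adjacency(m, beta=6)
        i, j, k = (net.genes.index(g) for g in ("a", "b", "c"))
        assert net.a[i, j] == pytest.approx(1.0)          # s = +1
        assert net.a[i, k] == pytest.approx(0.0, abs=1e-12)  # s = -1

    def test_zero_correlation_value(self):
        # s = 0, beta = 6 -> 0.5^6
        a = np.array([1.0, 1, -1, -1])
        b = np.array([1.0, -1, 1, -1])
        m = matrix_from_log2({"a": a + 2, "b": b + 2})
        net = coexnet.signed_adjacency(m, beta=6)
        assert net.a[0, 1] == pytest.approx(0.5 ** 6, abs=1e-12)

    def test_matches_elementwise_hand_computation(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(pd.DataFrame(rng.uniform(0, 50, (5, 12)),
                                          index=list("abcde")))
        net = coexnet.signed_adjacency(m, beta=4)
        x = np.log2(m.fpkm.to_numpy() + 1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert net.a[i, j] == 1.0
                    continue
                s = np.corrcoef(x[i], x[j])[0, 1]
                assert net.a[i, j] == pytest.approx((0.5 + 0.5 * s) ** 4, abs=1e-12)

    def test_constant_gene_excluded_with_warning(self):
        df = pd.DataFrame({"s1": [1.0, 5], "s2": [1.0, 6], "s3": [1.0, 7]},
                          index=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            net = coexnet.signed_adjacency(ExpressionMatrix(df), beta=2)
        assert net.genes == ["ok"]

    def test_beta_below_one_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="beta"):
            coexnet.signed_adjacency(toy_matrix, beta=0)


class TestScaleFreeFit:
    def test_exact_power_law_histogram(self):
        # k values drawn so bin frequencies follow p(k) ~ k^-2 exactly
        ks = np.concatenate([np.full(400, 1.0), np.full(100, 2.0),
                             np.full(44, 3.0), np.full(25, 4.0)])
        r2 = coexnet.scale_free_fit(ks, n_bins=4)
        assert r2 == pytest.approx(1.0, abs=1e-3)

    def test_uniform_connectivity_scores_low(self):
        ks = np.linspace(1, 100, 500)
        r2 = coexnet.scale_free_fit(ks, n_bins=10)
        assert r2 < 0.5

    def test_chosen_beta_beats_beta_one_on_simdata(self, default_sim):
        from snucseq import exprstats

        m, _s, _t = default_sim
        gated, _ = exprstats.gate_expressed(m)
        sub = m.subset_genes(sorted(gated))
        fit1 = coexnet.scale_free_fit(coexnet.signed_adjacency(sub, beta=1).k)
        fit6 = coexnet.scale_free_fit(coexnet.signed_adjacency(sub, beta=6).k)
        assert fit6 >= fit1


class TestTOM:
    def test_two_gene_network_tom_equals_adjacency(self):
        x = np.array([0.0, 1, 2, 3, 2])
        m = matrix_from_log2({"a": x, "b": x * 0.9 + 0.2})
        net = coexnet.signed_adjacency(m, beta=3)
        tom = coexnet.topological_overlap(net)
        assert tom[0, 1] == pytest.approx(net.a[0, 1], abs=1e-12)

    def test_complete_graph_tom_is_one(self):
        x = np.linspace(0, 4, 8)
        m = matrix_from_log2({g: x * c for g, c in
                              zip("abcd", [1.0, 2.0, 0.5, 1.5])})
        net = coexnet.signed_adjacency(m, beta=6)
        tom = coexnet.topological_overlap(net)
        np.testing.assert_allclose(tom, 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(pd.DataFrame(rng.uniform(0, 30, (6, 10))))
        net = coexnet.signed_adjacency(m, beta=6)
        tom = coexnet.topological_overlap(net)
        a, k = net.a, net.k
        n = len(net.genes)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(n)
                          if u not in (i, j)) + a[i, j]
                denom = min(k[i], k[j]) + 1 - a[i, j]
                assert tom[i, j] == pytest.approx(num / denom, abs=1e-10)


class TestDetectModules:
    def test_two_planted_blocks_found(self):
        m, labels = planted_module_matrix(seed=2)
        net = coexnet.signed_adjacency(m, beta=6)
        coexnet.topological_overlap(net)
        mods = coexnet.detect_modules(net, min_module_size=10)
        found = {}
        for g, b in labels.items():
            if b >= 0:
                found.setdefault(b, set()).add(mods.labels[g])
        assert all(len(v) == 1 for v in found.values())
        assert found[0] != found[1]

    def test_all_equal_tom_yields_no_modules(self):
        net = coexnet.NetworkModel(
            genes=[f"g{i}" for i in range(30)], beta=6,
            s=np.ones((30, 30)), a=np.ones((30, 30)), k=np.full(30, 29.0),
            tom=np.full((30, 30), 0.4))
        np.fill_diagonal(net.tom, 1.0)
        mods = coexnet.detect_modules(net, min_module_size=5)
        assert mods.module_names == []

    def test_small_block_below_min_size_unassigned(self):
        m, labels = planted_module_matrix(seed=3, sizes=(20, 10), n_noise=10)
        net = coexnet.signed_adjacency(m, beta=6)
        coexnet.topological_overlap(net)
        mods = coexnet.detect_modules(net, min_module_size=15)
        small_block = [g for g, b in labels.items() if b == 1]
        assert (mods.labels[small_block] == coexnet.UNASSIGNED).all()


class TestEigengene:
    def test_identical_genes_match_standardized_profile(self):
        x = np.array([0.0, 1, 3, 2, 4, 1])
        m = matrix_from_log2({"a": x, "b": x, "c": x})
        eig = coexnet.module_eigengene(m, ["a", "b", "c"])
        z = np.log2(m.fpkm.loc["a"].to_numpy() + 1)
        z = (z - z.mean()) / z.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_member_order(self, default_sim):
        m, _s, truth = default_sim
        members = [g for g, mo in truth.module_of_gene.items() if mo == "disease_1"]
        e1 = coexnet.module_eigengene(m, members)
        e2 = coexnet.module_eigengene(m, members[::-1])
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-9)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(pd.DataFrame(rng.uniform(0, 20, (3, 9)),
                                          index=["a", "b", "c"]))
        eig = coexnet.module_eigengene(m, ["a", "b", "c"])
        z = np.log2(m.fpkm.to_numpy() + 1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        _u, _s, vt = np.linalg.svd(z, full_matrices=False)
        assert abs(np.corrcoef(eig, vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_module_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 1.0], "s3": [1.0, 1.0]},
                          index=["a", "b"])
        with pytest.raises(ValueError, match="degenerate|constant"):
            coexnet.module_eigengene(ExpressionMatrix(df), ["a", "b"])


class TestPruneAndMerge:
    def _modset(self, matrix, assignment):
        return coexnet.ModuleSet(labels=pd.Series(assignment))

    def test_module_without_five_core_members_disbanded(self):
        m, _labels = planted_module_matrix(seed=5, sizes=(4,), n_noise=12)
        members = [f"g{i}" for i in range(4)]
        labels = {g: ("M1" if g in members else coexnet.UNASSIGNED)
                  for g in m.gene_ids}
        pruned = coexnet.prune_and_disband(m, self._modset(m, labels))
        assert pruned.module_names == []

    def test_kme_boundary_inclusive_at_030(self):
        # construct members whose kME to the module eigengene straddles 0.3
        rng = np.random.default_rng(6)
        n = 200
        latent = rng.normal(0, 1, n)
        cols = {}
        for i in range(8):
            cols[f"core{i}"] = 4 + latent + rng.normal(0, 0.2, n)
        cols["weak"] = 4 + 0.05 * latent + rng.normal(0, 1.0, n)
        m = matrix_from_log2(cols)
        labels = {g: "M1" for g in m.gene_ids}
        pruned = coexnet.prune_and_disband(m, self._modset(m, labels))
        kme_weak = np.corrcoef(
            np.log2(m.fpkm.loc["weak"] + 1),
            coexnet.module_eigengene(m, [g for g in m.gene_ids if g != "weak"]))[0, 1]
        if kme_weak < 0.3:
            assert pruned.labels["weak"] == coexnet.UNASSIGNED
        else:
            assert pruned.labels["weak"] == "M1"
        assert (pruned.labels[[f"core{i}" for i in range(8)]] == "M1").all()

    def test_split_module_remerged(self):
        m, labels = planted_module_matrix(seed=7, sizes=(30,), n_noise=5)
        members = [g for g, b in labels.items() if b == 0]
        assignment = {g: coexnet.UNASSIGNED for g in m.gene_ids}
        for g in members[:15]:
            assignment[g] = "M1"
        for g in members[15:]:
            assignment[g] = "M2"
        mods = coexnet.prune_and_disband(m, self._modset(m, assignment))
        merged = coexnet.merge_modules(m, mods)
        assert len(merged.module_names) == 1
        assert merged.merge_history

    def test_orthogonal_modules_not_merged(self):
        m, labels = planted_module_matrix(seed=8, sizes=(20, 20), n_noise=0)
        assignment = {g: f"M{b + 1}" for g, b in labels.items()}
        mods = coexnet.prune_and_disband(m, self._modset(m, assignment))
        merged = coexnet.merge_modules(m, mods)
        assert len(merged.module_names) == 2

    def test_exact_boundary_correlation_not_merged(self, monkeypatch):
        """Eigengene correlation exactly at 0.75 stays unmerged ('above')."""
        m, labels = planted_module_matrix(seed=9, sizes=(10, 10), n_noise=0)
        assignment = {g: f"M{b + 1}" for g, b in labels.items()}
        mods = coexnet.ModuleSet(labels=pd.Series(assignment))
        real_corr = pd.DataFrame.corr

        def fake_corr(self, *a, **k):
            out = real_corr(self, *a, **k)
            out[:] = np.where(np.eye(len(out), dtype=bool), 1.0, 0.75)
            return out

        monkeypatch.setattr(pd.DataFrame, "corr", fake_corr)
        merged = coexnet.merge_modules(m, mods)
        assert len(merged.module_names) == 2


class TestTraitsAndExport:
    def test_eigengene_equal_to_indicator_correlates_one(self, default_sim):
        m, s, truth = default_sim
        subgroups = s.table.set_index("sample_id")["subgroup"]
        indicator = (subgroups == "TAC_A").astype(float)
        labels = pd.Series(coexnet.UNASSIGNED, index=m.gene_ids)
        members = [g for g, mo in truth.module_of_gene.items() if mo == "disease_1"]
        labels[members] = "M1"
        mods = coexnet.ModuleSet(labels=labels)
        mods.eigengenes = pd.DataFrame({"M1": indicator})
        mods.kme = coexnet.kme_table(m, mods.eigengenes)
        assoc = coexnet.trait_association(m, mods, subgroups)
        assert assoc.module_trait_corr.loc["M1", "TAC_A"] == pytest.approx(1.0)
        assert assoc.module_assignment["M1"] == "TAC_A"

    def test_disease_module_assigned_to_planted_subgroup(self, default_sim):
        from snucseq import exprstats

        m, s, truth = default_sim
        gated, _ = exprstats.gate_expressed(m)
        sub = m.subset_genes(sorted(gated))
        _net, mods = coexnet.build_modules(sub, beta=6)
        subgroups = s.table.set_index("sample_id")["subgroup"]
        assoc = coexnet.trait_association(sub, mods, subgroups)
        hub = truth.hub_of_module["disease_1"]
        module_of_hub = mods.labels[hub]
        assert assoc.module_assignment[module_of_hub] == "TAC_A"

    def test_gs_of_top_kme_gene_exceeds_nonmember_median(self, default_sim):
        from snucseq import exprstats

        m, s, truth = default_sim
        gated, _ = exprstats.gate_expressed(m)
        sub = m.subset_genes(sorted(gated))
        _net, mods = coexnet.build_modules(sub, beta=6)
        subgroups = s.table.set_index("sample_id")["subgroup"]
        assoc = coexnet.trait_association(sub, mods, subgroups)
        hub = truth.hub_of_module["disease_1"]
        module = mods.labels[hub]
        trait = assoc.module_assignment[module]
        members = mods.members(module)
        top_gene = mods.kme.loc[members, module].idxmax()
        nonmembers = [g for g in sub.gene_ids if g not in set(members)]
        assert assoc.gs.loc[top_gene, trait] > assoc.gs.loc[nonmembers, trait].median()

    def test_single_subgroup_rejected(self, default_sim):
        m, _s, truth = default_sim
        labels = pd.Series(coexnet.UNASSIGNED, index=m.gene_ids)
        members = [g for g, mo in truth.module_of_gene.items() if mo == "healthy"]
        labels[members] = "M1"
        mods = coexnet.ModuleSet(labels=labels)
        mods.eigengenes = pd.DataFrame(
            {"M1": np.zeros(m.n_samples)}, index=m.sample_ids)
        with pytest.raises(ValueError, match="subgroup"):
            coexnet.trait_association(
                m, mods, pd.Series("only", index=m.sample_ids))

    def test_export_thresholds_and_round_trip(self, tmp_path):
        m, labels = planted_module_matrix(seed=10, sizes=(3,), n_noise=0)
        net = coexnet.signed_adjacency(m, beta=2)
        coexnet.topological_overlap(net)
        mods = coexnet.ModuleSet(labels=pd.Series({g: "M1" for g in m.gene_ids}))
        e1, _n1 = coexnet.export_network(mods, net, 1.0, tmp_path / "e1.tsv",
                                         tmp_path / "n1.tsv")
        assert len(e1) == 0
        e2, _n2 = coexnet.export_network(mods, net, 0.0, tmp_path / "e2.tsv",
                                         tmp_path / "n2.tsv")
        assert len(e2) == 3  # complete graph on 3 genes
        back = pd.read_csv(tmp_path / "e2.tsv", sep="\t")
        assert set(map(tuple, back[["gene1", "gene2"]].to_numpy())) == \
            set(map(tuple, e2[["gene1", "gene2"]].to_numpy()))
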