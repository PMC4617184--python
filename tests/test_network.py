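"""Co-expression network: soft threshold, topological overlap, module
detection, eigengenes, module-trait relationships, kME filtering and
hub-gene rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from eqtlnet.datatypes import ProcessedExpression
from eqtlnet.network import (
    adjacency_matrix,
    build_input_set,
    compute_kme,
    detect_modules,
    filter_module_membership,
    identify_hub_gene,
    module_eigengenes,
    module_trait_relationships,
    scale_free_fit,
    soft_threshold_scan,
    topological_overlap,
)
from eqtlnet.simulate import simulate_module_expression


def tom_triple_loop_oracle(a: np.ndarray) -> np.ndarray:
    """Literal triple-loop evaluation of the TOM formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _expr(values: pd.DataFrame) -> ProcessedExpression:
    return ProcessedExpression(values=values, provenance=["test"])


class TestBuildInputSet:
    def test_union_is_deduplicated_and_ordered(self):
        vals = pd.DataFrame(
            np.random.default_rng(0).normal(size=(6, 5)),
            index=[f"g{k}" for k in range(6)],
        )
        out = build_input_set(["g1", "g3"], ["g3", "g5", "g0"], _expr(vals))
        assert out.gene_ids == ["g0", "g1", "g3", "g5"]

    def test_disjoint_sets_add(self):
        vals = pd.DataFrame(
            np.zeros((7, 4)) + np.arange(4), index=[f"g{k}" for k in range(7)]
        )
        out = build_input_set(["g0", "g1", "g2"], ["g3", "g4", "g5", "g6"], _expr(vals))
        assert len(out.gene_ids) == 7

    def test_empty_union_rejected(self):
        vals = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(ValueError):
            build_input_set([], [], _expr(vals))

    def test_unknown_gene_rejected(self):
        vals = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(ValueError):
            build_input_set(["zzz"], [], _expr(vals))


class TestScaleFreeFit:
    def test_exact_power_law_gives_r2_one(self):
        """Connectivities arranged so occupied bins follow p(k) ~ k^-2."""
        ks, counts = [], []
        for b in range(10):
            k = 10.0 + 10.0 * b  # bin centers 10, 20, ..., 100
            c = int(round(1e6 * k ** -2.0))
            ks.extend([k] * c)
        r2 = scale_free_fit(np.array(ks), n_bins=10)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_positive_slope_reported_negative(self):
        ks = []
        for b in range(10):
            k = 10.0 + 10.0 * b
            ks.extend([k] * int(k**2 / 10))
        assert scale_free_fit(np.array(ks), n_bins=10) < 0

    def test_collapsed_distribution_scores_zero(self):
        k = np.concatenate([np.full(200, 1e-4), [1.0]])
        assert scale_free_fit(k, n_bins=10) == 0.0


class TestSoftThresholdScan:
    def test_smallest_beta_reaching_target_is_chosen(self):
        rng = np.random.default_rng(1)
        vals, _ = simulate_module_expression([40, 30], 30, 30, 0.7, rng=rng)
        beta, table = soft_threshold_scan(
            _expr(vals), candidate_betas=range(1, 15), target_r2=0.3
        )
        reached = table[table["r_squared"] >= 0.3]
        assert beta == int(reached["beta"].iloc[0])

    def test_fallback_avoids_degenerate_powers(self):
        rng = np.random.default_rng(2)
        vals, _ = simulate_module_expression([40, 30], 30, 30, 0.7, rng=rng)
        beta, table = soft_threshold_scan(_expr(vals), target_r2=0.999)
        assert table.loc[table["beta"] == beta, "mean_k"].iloc[0] >= 1.0

    def test_constant_genes_dropped(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(
            rng.normal(size=(40, 20)), index=[f"g{k}" for k in range(40)]
        )
        vals.iloc[0] = 5.0  # constant gene
        beta, table = soft_threshold_scan(_expr(vals), candidate_betas=[1, 2])
        assert len(table) == 2


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        n = 5
        a = pd.DataFrame(np.ones((n, n)), index=list("abcde"), columns=list("abcde"))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    def test_empty_graph_is_identity(self):
        a = pd.DataFrame(np.eye(4))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom.to_numpy(), np.eye(4))

    def test_three_gene_hand_example(self):
        """a12 = a13 = 0.5, a23 = 0 -> tom12 = 0.5/(0.5 + 1 - 0.5) = 0.5."""
        a = pd.DataFrame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]],
            index=list("xyz"),
            columns=list("xyz"),
        )
        tom = topological_overlap(a)
        assert tom.loc["x", "y"] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.uniform(size=(12, 12))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            adf = pd.DataFrame(a)
            diff = np.abs(
                topological_overlap(adf).to_numpy() - tom_triple_loop_oracle(a)
            )
            assert diff.max() < 1e-12

    def test_disjoint_edges_equal_adjacency(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.7
        a[2, 3] = a[3, 2] = 0.3
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(tom, a, atol=1e-12)

    def test_bounds_hold(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_higher_beta_is_sparser(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(size=(30, 20)))
        means = [
            adjacency_matrix(vals, b).to_numpy().mean() for b in (1, 2, 4, 8)
        ]
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))


class TestDetectModules:
    def test_two_perfect_blocks(self):
        """Within-TOM 1, between-TOM 0 recovers exact memberships."""
        n1, n2 = 30, 40
        tom = np.zeros((n1 + n2, n1 + n2))
        tom[:n1, :n1] = 1.0
        tom[n1:, n1:] = 1.0
        genes = [f"g{k}" for k in range(n1 + n2)]
        labels = detect_modules(pd.DataFrame(tom, index=genes, columns=genes), min_size=25)
        assert labels.iloc[0] != labels.iloc[-1]
        assert (labels != 0).all()
        # module 1 is the larger block
        assert (labels == 1).sum() == n2 and (labels == 2).sum() == n1

    def test_fewer_genes_than_min_size_all_unassigned(self):
        tom = pd.DataFrame(np.eye(20))
        labels = detect_modules(tom, min_size=25)
        assert (labels == 0).all()

    def test_gene_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(7)
        vals, truth = simulate_module_expression([40, 30], 20, 30, 0.8, rng=rng)
        adj = adjacency_matrix(vals, 6)
        tom = topological_overlap(adj)
        l1 = detect_modules(tom, min_size=20)
        perm = rng.permutation(len(vals))
        genes_p = [vals.index[i] for i in perm]
        tom_p = tom.loc[genes_p, genes_p]
        l2 = detect_modules(tom_p, min_size=20).loc[l1.index]
        assert adjusted_rand_score(l1.to_numpy(), l2.to_numpy()) == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        vals = pd.DataFrame([profile] * 4, index=[f"g{k}" for k in range(4)])
        labels = pd.Series([1] * 4, index=vals.index)
        eig, varexp = module_eigengenes(vals, labels)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.loc[1].to_numpy(), z, atol=1e-10)
        assert varexp[1] == pytest.approx(1.0)

    def test_orientation_gives_nonnegative_mean_kme(self):
        rng = np.random.default_rng(8)
        vals, truth = simulate_module_expression([30], 0, 25, 0.6, rng=rng)
        labels = pd.Series([truth[g] for g in vals.index], index=vals.index)
        eig, _ = module_eigengenes(vals, labels)
        kme = compute_kme(vals, eig)
        assert kme.loc[labels == 1, 1].mean() >= 0

    def test_two_anticorrelated_genes_split_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = pd.DataFrame([x, -x], index=["up", "down"])
        labels = pd.Series([1, 1], index=vals.index)
        eig, varexp = module_eigengenes(vals, labels)
        # perfectly anti-correlated pair: PC1 explains exactly half... of
        # nothing else: |cor| with both genes is 1, variance split 1/0
        u, s, vt = np.linalg.svd(
            np.vstack([(x - x.mean()) / x.std(), (-x + x.mean()) / x.std()])
        )
        expected = s[0] ** 2 / (s**2).sum()
        assert varexp[1] == pytest.approx(expected)


class TestModuleTraitRelationships:
    def _eig(self, rows):
        return pd.DataFrame(
            rows,
            index=pd.Index(range(1, len(rows) + 1), name="module"),
            columns=[f"s{j}" for j in range(len(rows[0]))],
        )

    def test_eigengene_equal_to_trait_is_selected(self):
        oi = np.linspace(-1, 1, 12)
        eig = self._eig([(oi - oi.mean()) / oi.std()])
        traits = pd.DataFrame({"oi": oi}, index=eig.columns)
        mtr, p, selected = module_trait_relationships(eig, traits)
        assert mtr.loc[1, "oi"] == pytest.approx(1.0)
        assert (1, "oi") in selected

    def test_exactly_half_correlation_not_selected(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= e @ x / (x @ x) * x  # orthogonalize
        x = (x - x.mean()) / x.std()
        e = (e - e.mean()) / e.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * e
        eig = self._eig([x])
        traits = pd.DataFrame({"t": y}, index=eig.columns)
        mtr, p, selected = module_trait_relationships(eig, traits)
        assert mtr.loc[1, "t"] == pytest.approx(0.5, abs=0.02)
        mtr2, _, sel2 = module_trait_relationships(eig, traits, select_threshold=abs(mtr.loc[1, "t"]))
        assert (1, "t") not in sel2  # strict inequality at the boundary

    def test_constant_trait_reported_missing(self):
        eig = self._eig([np.linspace(0, 1, 8)])
        traits = pd.DataFrame({"flat": np.ones(8)}, index=eig.columns)
        mtr, p, selected = module_trait_relationships(eig, traits)
        assert np.isnan(mtr.loc[1, "flat"]) and not selected


class TestMembershipAndHubs:
    def _kme(self):
        return pd.DataFrame(
            {1: [0.65, 0.55, 0.9, 0.95], 2: [0.30, 0.10, 0.8, 0.2]},
            index=["keep", "weak_own", "cross", "hubby"],
        )

    def test_retention_rules(self):
        kme = self._kme()
        labels = pd.Series([1, 1, 1, 1], index=kme.index)
        out = filter_module_membership(kme, labels, own_min=0.6, other_max=0.6)
        assert out["keep"] == 1
        assert out["weak_own"] == 0  # own kME 0.55 <= 0.6
        assert out["cross"] == 0  # other-module kME 0.8 >= 0.6
        assert out["hubby"] == 1

    def test_literal_other_rule_flips_cross_behavior(self):
        kme = self._kme()
        labels = pd.Series([1, 1, 1, 1], index=kme.index)
        out = filter_module_membership(
            kme, labels, own_min=0.6, other_max=0.6, literal_other_rule=True
        )
        assert out["cross"] == 1 and out["keep"] == 0

    def test_hub_by_connectivity_with_tie_break(self):
        conn = pd.Series({"b": 5.0, "a": 5.0, "c": 1.0})
        kme_own = pd.Series({"a": 0.85, "b": 0.7, "c": 0.5})
        trait_cor = pd.Series({"a": 0.65, "b": 0.3, "c": 0.1})
        hub, eligible = identify_hub_gene(["a", "b", "c"], conn, kme_own, trait_cor)
        assert hub == "a"  # lexicographic tie-break at equal connectivity
        assert eligible == ["a"]  # kME > 0.8 AND |trait cor| > 0.6

    def test_boundary_values_not_eligible(self):
        conn = pd.Series({"a": 1.0})
        hub, eligible = identify_hub_gene(
            ["a"], conn, pd.Series({"a": 0.8}), pd.Series({"a": 0.9})
        )
        assert eligible == []
        hub, eligible = identify_hub_gene(
            ["a"], conn, pd.Series({"a": 0.9}), pd.Series({"a": 0.6})
        )
        assert eligible == []
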