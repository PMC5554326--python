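"""Conservation statistics: CVs, null models, permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import menconserve as mc
from conftest import net_from_edges
from menconserve.conservation import pairwise_coefficient_matrix


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert mc.coefficient_of_variation([5, 5, 5, 5]) == 0.0

    def test_known_value(self):
        assert mc.coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        x = [2.0, 3.5, 5.0, 7.25]
        assert mc.coefficient_of_variation([7 * v for v in x]) == pytest.approx(
            mc.coefficient_of_variation(x)
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            mc.coefficient_of_variation([-1, 1])


class TestMaslovSneppen:
    def random_net(self, seed, n=20, p=0.25):
        import networkx as nx

        g = nx.gnp_random_graph(n, p, seed=seed)
        while g.number_of_edges() < 2:
            seed += 1000
            g = nx.gnp_random_graph(n, p, seed=seed)
        return net_from_edges(list(g.edges))

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_sequence_exactly_preserved(self, seed):
        net = self.random_net(seed)
        rewired = mc.maslov_sneppen_rewire(net, swap_factor=20, seed=seed)
        assert rewired.n_nodes == net.n_nodes
        assert rewired.n_edges == net.n_edges
        assert sorted(d for _, d in rewired.graph.degree()) == sorted(
            d for _, d in net.graph.degree()
        )
        assert not any(a == b for a, b in rewired.graph.edges)

    def test_rewiring_changes_edges_and_is_seeded(self):
        net = self.random_net(0, n=30, p=0.2)
        a = mc.maslov_sneppen_rewire(net, seed=1)
        b = mc.maslov_sneppen_rewire(net, seed=1)
        c = mc.maslov_sneppen_rewire(net, seed=2)
        assert set(map(frozenset, a.graph.edges)) == set(map(frozenset, b.graph.edges))
        assert set(map(frozenset, a.graph.edges)) != set(map(frozenset, net.graph.edges))
        assert set(map(frozenset, a.graph.edges)) != set(map(frozenset, c.graph.edges))

    def test_tiny_network_returned_unchanged(self):
        net = net_from_edges([(0, 1)])
        with pytest.warns(UserWarning):
            out = mc.maslov_sneppen_rewire(net, seed=0)
        assert set(out.graph.edges) == {(0, 1)}


class TestNullCvEnsemble:
    def nets(self):
        import networkx as nx

        out = {}
        for k, g in enumerate(["G1", "G2", "G3", "G4"]):
            graph = nx.gnp_random_graph(16, 0.3, seed=k)
            out[g] = net_from_edges(list(graph.edges), group=g)
        return out

    def test_rewiring_invariant_index_gives_zero_null_sd(self):
        mean, sd, cvs = mc.null_cv_ensemble(self.nets(), "n_edges", n_reps=5, seed=0)
        observed = mc.coefficient_of_variation([n.n_edges for n in self.nets().values()])
        assert sd == 0.0
        assert mean == pytest.approx(observed)

    def test_avg_gd_null_has_positive_spread(self):
        mean, sd, cvs = mc.null_cv_ensemble(self.nets(), "avg_gd", n_reps=20, seed=0)
        assert sd > 0
        assert all(cv >= 0 for cv in cvs)
        assert len(cvs) == 20

    def test_multi_index_ensemble_matches_single(self):
        nets = self.nets()
        multi = mc.null_cv_ensembles(nets, ["avg_gd", "avg_cc"], n_reps=10, seed=3)
        single = mc.null_cv_ensemble(nets, "avg_gd", n_reps=10, seed=3)
        assert multi["avg_gd"][2] == pytest.approx(single[2])


class TestCvTtest:
    def test_equal_cvs_null_case(self):
        t, p = mc.cv_ttest(0.5, 0.1, 0.5, 0.1, n_reps=100)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_large_separation_is_significant(self):
        t, p = mc.cv_ttest(1.0, 0.05, 0.5, 0.05, n_reps=100)
        assert p < 0.001

    def test_antisymmetry(self):
        t1, p1 = mc.cv_ttest(0.8, 0.1, 0.5, 0.2, n_reps=50)
        t2, p2 = mc.cv_ttest(0.5, 0.2, 0.8, 0.1, n_reps=50)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_spread(self):
        assert mc.cv_ttest(0.4, 0.0, 0.4, 0.0) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            t, p = mc.cv_ttest(0.5, 0.0, 0.4, 0.0)
        assert p == 0.0


class TestSharedNodes:
    def test_strictly_more_than_three_networks(self):
        presence = {"a": 6, "b": 4, "c": 3, "d": 1}
        assert mc.shared_nodes(presence) == {"a", "b"}

    def test_threshold_configurable(self):
        assert mc.shared_nodes({"a": 2, "b": 1}, min_networks=1) == {"a"}


class TestNodeCvComparison:
    def test_identical_ranks_give_zero_cvs(self):
        mat = pd.DataFrame({"G1": [10.0, 50.0], "G2": [10.0, 50.0]}, index=["a", "b"])
        cvs, _ = mc.node_cv_comparison({"layer": mat})
        assert np.allclose(cvs.to_numpy(), 0.0)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.uniform(1, 100, size=(40, 6)))
        mat.index = [f"n{i}" for i in range(40)]
        cvs, wilcoxon = mc.node_cv_comparison({"a": mat, "b": mat.copy()})
        assert wilcoxon[("a", "b")] == pytest.approx(1.0)

    def test_nodes_present_in_fewer_than_two_groups_excluded(self):
        mat = pd.DataFrame(
            {"G1": [10.0, 20.0], "G2": [np.nan, 30.0]}, index=["lonely", "ok"]
        )
        cvs, _ = mc.node_cv_comparison({"layer": mat})
        assert ("layer", "lonely") not in cvs.index
        assert ("layer", "ok") in cvs.index


class TestCrossValidateRanks:
    def matrix(self, low, high, nodes=None):
        nodes = nodes or [f"n{i}" for i in range(len(low))]
        return pd.DataFrame(
            {
                "G1": low, "G2": low, "G3": low,
                "G4": high, "G5": high, "G6": high,
            },
            index=nodes,
        )

    def test_identical_halves_lie_on_diagonal(self):
        mat = self.matrix([10.0, 40.0, 90.0], [10.0, 40.0, 90.0])
        cv = mc.cross_validate_ranks(mat, ["G1", "G2", "G3"], ["G4", "G5", "G6"])
        assert np.allclose(cv.d_values, 0.0)
        assert cv.band_fraction == 1.0
        assert cv.slope == pytest.approx(1.0)

    def test_distance_geometry_and_strict_band(self):
        mat = self.matrix([10.0, 50.0], [30.0, 50.0])
        cv = mc.cross_validate_ranks(mat, ["G1", "G2", "G3"], ["G4", "G5", "G6"])
        assert cv.d_values.iloc[0] == pytest.approx(20 / np.sqrt(2))
        # |x - y| = 20 is NOT strictly inside the default 20-unit band
        assert cv.band_fraction == pytest.approx(0.5)

    def test_vertical_metric_option(self):
        mat = self.matrix([10.0, 50.0], [30.0, 50.0])
        cv = mc.cross_validate_ranks(
            mat, ["G1", "G2", "G3"], ["G4", "G5", "G6"], d_metric="vertical"
        )
        assert cv.d_values.iloc[0] == pytest.approx(20.0)

    def test_node_missing_entire_half_excluded(self):
        mat = self.matrix([10.0, 40.0], [20.0, 50.0])
        mat.loc["n0", ["G4", "G5", "G6"]] = np.nan
        cv = mc.cross_validate_ranks(mat, ["G1", "G2", "G3"], ["G4", "G5", "G6"])
        assert cv.excluded == ["n0"]
        assert list(cv.points.index) == ["n1"]


class TestPairwiseCorrelationCv:
    def corrs(self, values_by_group):
        out = {}
        for g, r01 in values_by_group.items():
            r = np.array([[1.0, r01], [r01, 1.0]])
            out[g] = mc.CorrelationMatrix(feature_ids=("a", "b"), r=r, n_samples=6)
        return out

    def test_constant_coefficient_zero_cv(self):
        corrs = self.corrs({g: 0.5 for g in "ABCDEF"})
        cvs, excluded = mc.pairwise_correlation_cv(corrs, ["a", "b"])
        assert cvs.iloc[0] == pytest.approx(0.0)
        assert excluded == 0

    def test_printed_arithmetic(self):
        corrs = self.corrs(dict(zip("ABCDEF", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])))
        cvs, _ = mc.pairwise_correlation_cv(corrs, ["a", "b"])
        assert cvs.iloc[0] == pytest.approx(0.5345, abs=1e-4)

    def test_near_zero_mean_pair_excluded(self):
        corrs = self.corrs(dict(zip("ABCD", [0.5, -0.5, 0.5, -0.5])))
        cvs, excluded = mc.pairwise_correlation_cv(corrs, ["a", "b"])
        assert excluded == 1
        assert len(cvs) == 0

    def test_abs_mode_rescues_sign_flippers(self):
        corrs = self.corrs(dict(zip("ABCD", [0.5, -0.5, 0.5, -0.5])))
        cvs, excluded = mc.pairwise_correlation_cv(corrs, ["a", "b"], use_abs=True)
        assert excluded == 0
        assert cvs.iloc[0] == pytest.approx(0.0)

    def test_anova_detects_dispersion_difference(self):
        # coefficients with doubled across-group dispersion yield higher
        # pair-CVs, which the across-layer ANOVA picks up
        rng = np.random.default_rng(0)

        def layer_cvs(spread):
            coeffs = 0.5 + rng.normal(0, spread, size=(60, 6))
            return coeffs.std(axis=1, ddof=1) / coeffs.mean(axis=1)

        f, p = mc.compare_cv_distributions_anova(
            {"tight": layer_cvs(0.05), "loose": layer_cvs(0.10)}
        )
        assert p < 0.05


class TestCorrelationRandomizationTest:
    def test_conserved_rows_vs_heterogeneous_columns_minimum_p(self):
        rng = np.random.default_rng(0)
        col_levels = np.linspace(0.1, 0.9, 6)
        rows = np.tile(rng.uniform(0.2, 0.8, size=(50, 1)), (1, 6))
        coeffs = pd.DataFrame(rows + 0.001 * rng.normal(size=rows.shape))
        obs, p = mc.correlation_randomization_test(coeffs, n_perm=999, seed=1)
        assert p == pytest.approx(0.001)

    def test_defaults_match_design(self):
        import inspect

        sig = inspect.signature(mc.correlation_randomization_test)
        assert sig.parameters["n_perm"].default == 999

    def test_missing_cells_handled_with_fixed_mask(self):
        rng = np.random.default_rng(2)
        coeffs = pd.DataFrame(rng.uniform(0.1, 0.9, size=(30, 6)))
        coeffs.iloc[0, 0] = np.nan
        coeffs.iloc[5, 3] = np.nan
        obs, p = mc.correlation_randomization_test(coeffs, n_perm=99, seed=0)
        assert 0 < p <= 1

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            mc.correlation_randomization_test(pd.DataFrame([[0.5, 0.5]]), n_perm=9, seed=0)


class TestPairwiseCoefficientMatrix:
    def test_missing_pairs_are_nan(self):
        r2 = np.array([[1.0, 0.4], [0.4, 1.0]])
        r3 = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.7], [0.6, 0.7, 1.0]])
        corrs = {
            "G1": mc.CorrelationMatrix(feature_ids=("a", "b"), r=r2, n_samples=6),
            "G2": mc.CorrelationMatrix(feature_ids=("a", "b", "c"), r=r3, n_samples=6),
        }
        mat = pairwise_coefficient_matrix(corrs, ["a", "b", "c"])
        assert mat.loc[("a", "b"), "G1"] == pytest.approx(0.4)
        assert np.isnan(mat.loc[("a", "c"), "G1"])
        assert mat.loc[("b", "c"), "G2"] == pytest.approx(0.7)
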