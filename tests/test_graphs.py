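import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import signedconn as sc
from _oracles import clustering_bf, local_efficiency_bf, participation_bf
from conftest import random_symmetric
from signedconn.graphs import (
    apply_distance_exclusion,
    build_signed_network,
    construct_network,
    distance_mask,
    proportional_threshold,
)


def as_masked(w):
    v = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(v, np.nan)
    return v


class TestDistanceExclusion:
    def test_close_pair_removed_everywhere(self, parcellation_small):
        parc = parcellation_small
        d = squareform(pdist(parc.volume_xyz))
        iu = np.triu_indices(parc.n_nodes, 1)
        close = np.argwhere((d < 30) & np.triu(np.ones_like(d, bool), 1))
        assert close.size > 0, "fixture should contain close pairs"
        w = np.abs(random_symmetric(np.random.default_rng(0), parc.n_nodes, 1.0)) + 1.0
        masked, mask = apply_distance_exclusion(w, parc, 30.0)
        i, j = close[0]
        assert np.isnan(masked[i, j])
        net = proportional_threshold(masked, density=1.0)
        assert net.weights[i, j] == 0.0
        assert sc.node_strength(masked, "positive")[i] < w[i].sum() - 1e-12

    def test_zero_radius_is_identity(self, parcellation_small):
        w = random_symmetric(np.random.default_rng(1), parcellation_small.n_nodes)
        masked, mask = apply_distance_exclusion(w, parcellation_small, 0.0)
        assert not mask.any()
        off = ~np.eye(w.shape[0], dtype=bool)
        assert np.array_equal(masked[off], w[off])

    def test_matches_brute_force_pair_enumeration(self, parcellation_small):
        parc = parcellation_small
        mask = distance_mask(parc, 30.0)
        expected = np.zeros_like(mask)
        for i in range(parc.n_nodes):
            for j in range(parc.n_nodes):
                if i != j and np.linalg.norm(
                        parc.volume_xyz[i] - parc.volume_xyz[j]) < 30.0:
                    expected[i, j] = True
        assert np.array_equal(mask, expected)

    def test_missing_coordinates_error(self, parcellation_small):
        import dataclasses

        broken = dataclasses.replace(parcellation_small, volume_xyz=None)
        with pytest.raises(ValueError, match="coordinates"):
            distance_mask(broken)


class TestConstructNetwork:
    def test_sign_treatments_on_negative_edge(self):
        w = as_masked([[0, -0.4], [-0.4, 0]])
        assert construct_network(w, "absolute")[0, 1] == pytest.approx(0.4)
        assert construct_network(w, "positive_only")[0, 1] == 0.0

    def test_all_positive_matrix_treatments_agree(self, rng):
        w = as_masked(np.abs(random_symmetric(rng, 10)))
        a = construct_network(w, "absolute")
        p = construct_network(w, "positive_only")
        assert np.allclose(np.nan_to_num(a), np.nan_to_num(p))

    def test_positive_only_dominated_by_absolute(self, rng):
        for _ in range(10):
            w = as_masked(random_symmetric(rng, 12, signed=True))
            a = np.nan_to_num(construct_network(w, "absolute"))
            p = np.nan_to_num(construct_network(w, "positive_only"))
            assert np.all(p <= a + 1e-15)

    def test_unknown_treatment(self):
        with pytest.raises(ValueError, match="treatment"):
            construct_network(as_masked(np.zeros((3, 3))), "signed")


class TestProportionalThreshold:
    def test_small_graph_keeps_top_half(self):
        w = np.array([
            [0, .9, .1, .5],
            [.9, 0, .8, .2],
            [.1, .8, 0, .3],
            [.5, .2, .3, 0.]])
        net = proportional_threshold(as_masked(w), density=0.5)
        assert net.n_retained == 3
        kept = sorted(net.weights[np.triu_indices(4, 1)], reverse=True)[:3]
        assert kept == [0.9, 0.8, 0.5]
        assert net.weights[0, 2] == 0.0

    def test_density_one_keeps_everything(self, rng):
        w = as_masked(np.abs(random_symmetric(rng, 8, 1.0)) + 0.01)
        net = proportional_threshold(w, density=1.0)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(net.weights[off], w[off])
        assert net.density == pytest.approx(1.0)

    def test_matches_sort_and_cut_oracle(self, rng):
        w = as_masked(np.abs(random_symmetric(rng, 50, 1.0)) + 1e-6)
        net = proportional_threshold(w, density=0.25)
        iu = np.triu_indices(50, 1)
        vals = w[iu]
        k = int(np.floor(0.25 * vals.size))
        cutoff = np.sort(vals)[::-1][k - 1]
        expected = set(map(tuple, np.argwhere(np.triu(w >= cutoff, 1))))
        got = set(map(tuple, np.argwhere(np.triu(net.weights > 0, 1))))
        assert got == expected

    def test_weights_not_binarized(self, rng):
        w = as_masked(np.abs(random_symmetric(rng, 10, 1.0)) + 0.01)
        net = proportional_threshold(w, density=0.5)
        kept = net.weights[net.weights > 0]
        assert np.unique(kept).size > 1

    def test_zero_edge_budget_error(self):
        w = as_masked(np.abs(np.ones((3, 3))))
        with pytest.raises(ValueError, match="zero"):
            proportional_threshold(w, density=0.01)

    def test_deterministic_tie_break(self):
        w = as_masked(np.full((6, 6), 0.5))
        a = proportional_threshold(w, density=0.3)
        b = proportional_threshold(w, density=0.3)
        assert np.array_equal(a.weights, b.weights)
        assert a.n_retained == int(np.floor(0.3 * 15))


class TestMetrics:
    def test_unit_triangle_clustering(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(sc.clustering_coefficient(w), 1.0)

    def test_star_graph_clustering_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.7
        assert np.allclose(sc.clustering_coefficient(w), 0.0)

    def test_unit_triangle_local_efficiency(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(sc.local_efficiency(w), 1.0)

    def test_path_center_local_efficiency_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert sc.local_efficiency(w)[1] == 0.0

    def test_participation_own_module_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        modules = np.array([0, 0, 1, 1])
        assert sc.participation_coefficient(w, modules)[0] == 0.0

    def test_participation_even_two_way_split(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        w[0, 2] = w[2, 0] = 0.4
        modules = np.array([0, 0, 1])
        assert sc.participation_coefficient(w, modules)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("m", range(2, 14))
    def test_participation_even_m_way_split(self, m):
        w = np.zeros((m + 1, m + 1))
        w[0, 1:] = w[1:, 0] = 0.3
        modules = np.array([0] + list(range(m)))
        pi = sc.participation_coefficient(w, modules)[0]
        assert pi == pytest.approx(1 - 1 / m, abs=1e-12)

    def test_missing_module_error(self):
        with pytest.raises(ValueError, match="module"):
            sc.participation_coefficient(np.ones((3, 3)) - np.eye(3), np.array([0, 1]))

    def test_brute_force_oracles_small_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            w = np.abs(random_symmetric(rng, n, density=float(rng.uniform(0.3, 0.9))))
            modules = rng.integers(0, 3, size=n)
            assert np.allclose(sc.clustering_coefficient(w), clustering_bf(w), atol=1e-10)
            assert np.allclose(sc.local_efficiency(w), local_efficiency_bf(w), atol=1e-10)
            assert np.allclose(sc.participation_coefficient(w, modules),
                               participation_bf(w, modules), atol=1e-10)

    def test_clustering_matches_networkx(self, rng):
        import networkx as nx

        w = np.abs(random_symmetric(rng, 12, density=0.5))
        g = nx.from_numpy_array(w)
        nx_c = np.array([nx.clustering(g, weight="weight")[i] for i in range(12)])
        assert np.allclose(sc.clustering_coefficient(w), nx_c, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        w = np.abs(random_symmetric(rng, 10, density=0.6))
        modules = rng.integers(0, 3, size=10)
        perm = rng.permutation(10)
        wp = w[np.ix_(perm, perm)]
        for func in (sc.clustering_coefficient, sc.local_efficiency):
            assert np.allclose(func(wp), func(w)[perm], atol=1e-12)
        assert np.allclose(sc.participation_coefficient(wp, modules[perm]),
                           sc.participation_coefficient(w, modules)[perm], atol=1e-12)

    def test_scale_invariance_after_normalization(self, rng):
        w = np.abs(random_symmetric(rng, 10, density=0.6))
        for func in (sc.clustering_coefficient, sc.local_efficiency):
            assert np.allclose(func(3.7 * w), func(w), atol=1e-12)
        assert np.allclose(sc.participation_coefficient(3.7 * w, np.zeros(10, int)),
                           sc.participation_coefficient(w, np.zeros(10, int)),
                           atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        w = np.abs(random_symmetric(rng, 15, density=0.5))
        c = sc.clustering_coefficient(w)
        pi = sc.participation_coefficient(w, rng.integers(0, 4, 15))
        assert np.all((c >= 0) & (c <= 1))
        assert np.all((pi >= 0) & (pi <= 1))
        assert np.all(sc.local_efficiency(w) >= 0)


class TestSignedGraphMetricsTransformer:
    def test_pipeline_on_sessions(self, cohort_small):
        parc = cohort_small.parcellation
        mats = cohort_small.matrices()
        sgm = sc.SignedGraphMetrics(parcellation=parc, treatment="positive_only",
                                    density=0.25).fit(mats)
        panels = sgm.transform(mats)
        assert set(panels) == {"clustering", "local_efficiency", "participation"}
        for panel in panels.values():
            assert panel.shape == (cohort_small.n_sessions, parc.n_nodes)
            assert np.isfinite(panel).all()
        assert np.all(sgm.realized_densities_ <= 0.25 + 1e-12)

    def test_realized_density_within_one_edge(self, cohort_small):
        parc = cohort_small.parcellation
        mats = cohort_small.matrices()[:5]
        for treatment in ("absolute", "positive_only"):
            for mat in mats:
                m = mat.copy()
                np.fill_diagonal(m, np.nan)
                from signedconn.connectivity import ConnectivityMatrix, fisher_z

                z = fisher_z(ConnectivityMatrix(values=m)).values
                z[distance_mask(parc, 30.0)] = np.nan
                net = proportional_threshold(construct_network(z, treatment), 0.25)
                assert abs(net.density - 0.25) <= 1.0 / net.n_eligible

    def test_positive_only_edges_originate_positive(self, cohort_small):
        parc = cohort_small.parcellation
        mat = cohort_small.matrices()[0]
        net = build_signed_network(mat, parc, "positive_only", 0.25)
        i, j = np.nonzero(net.weights)
        assert np.all(mat[i, j] > 0)

    def test_invalid_parameters(self, cohort_small):
        mats = cohort_small.matrices()[:1]
        with pytest.raises(ValueError):
            sc.SignedGraphMetrics(parcellation=cohort_small.parcellation,
                                  treatment="negify").fit(mats)
        with pytest.raises(ValueError):
            sc.SignedGraphMetrics(parcellation=cohort_small.parcellation,
                                  metrics=("bogus",)).fit(mats)


def test_local_efficiency_cbrt_variant(rng):
    """The cube-root edge-length variant is a monotone reweighting: it agrees
    on unit-weight graphs and stays nonnegative elsewhere."""
    tri = np.ones((3, 3)) - np.eye(3)
    assert np.allclose(sc.local_efficiency(tri, edge_length="inverse_cbrt"), 1.0)
    w = np.abs(random_symmetric(rng, 10, density=0.6))
    out = sc.local_efficiency(w, edge_length="inverse_cbrt")
    assert np.all(out >= 0)
    with pytest.raises(ValueError, match="edge_length"):
        sc.local_efficiency(w, edge_length="sqrt")


def test_threshold_sweep_densities(rng):
    from signedconn.graphs import threshold_sweep

    w = as_masked(np.abs(random_symmetric(rng, 30, 1.0)) + 1e-6)
    nets = threshold_sweep(w, densities=(0.1, 0.25, 0.4))
    assert set(nets) == {0.1, 0.25, 0.4}
    counts = [nets[d].n_retained for d in (0.1, 0.25, 0.4)]
    assert counts == sorted(counts)
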