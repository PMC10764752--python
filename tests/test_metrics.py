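"""Weighted topology metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import make_graph
from fconn.connectivity import WeightedGraph
from fconn.metrics import (
    GLOBAL_METRICS,
    UndefinedMetricError,
    assortativity,
    auc_over_densities,
    betweenness,
    clustering_coefficient,
    clustering_per_node,
    compute_subject_metrics,
    global_efficiency,
    local_efficiency,
    modularity,
    modularity_q,
    nodal_efficiency,
    nodal_metrics,
    normalize_graph,
    path_length,
    path_length_full,
    shortest_distances,
    strength,
)


def wg(w, density=1.0):
    return WeightedGraph(w=np.asarray(w, dtype=float), density=density)


K4 = wg(np.ones((4, 4)) - np.eye(4))
_star = np.zeros((4, 4))
_star[0, 1:] = 1.0
STAR = wg(_star + _star.T)
PATH3 = wg([[0, 0.5, 0], [0.5, 0, 0.25], [0, 0.25, 0]])
TRI2 = wg(
    (lambda m: m + m.T)(
        np.array(
            [
                [0, 1, 1, 0, 0, 0],
                [0, 0, 1, 0, 0, 0],
                [0, 0, 0, 0, 0, 0],
                [0, 0, 0, 0, 1, 1],
                [0, 0, 0, 0, 0, 1],
                [0, 0, 0, 0, 0, 0],
            ],
            dtype=float,
        )
    )
)


class TestClosedFormAnchors:
    def test_complete_unit_graph(self):
        assert global_efficiency(K4) == pytest.approx(1.0)
        assert local_efficiency(K4) == pytest.approx(1.0)
        assert path_length(K4) == pytest.approx(1.0)
        assert clustering_coefficient(K4) == pytest.approx(1.0)
        nm = nodal_metrics(K4)
        assert np.allclose(nm["strength"], 3.0)
        assert np.allclose(nm["betweenness"], 0.0)
        assert np.allclose(nm["nodal_efficiency"], 1.0)

    def test_star_graph(self):
        assert assortativity(STAR) == pytest.approx(-1.0)
        assert local_efficiency(STAR) == pytest.approx(0.0)
        assert clustering_coefficient(STAR) == pytest.approx(0.0)

    def test_regular_ring_assortativity_undefined(self):
        ring = np.zeros((5, 5))
        for i in range(5):
            ring[i, (i + 1) % 5] = ring[(i + 1) % 5, i] = 1.0
        with pytest.raises(UndefinedMetricError):
            assortativity(wg(ring))

    def test_two_disconnected_triangles_q_half(self):
        part = modularity(TRI2, n_restarts=10, seed=0)
        assert part.q == pytest.approx(0.5)
        assert len(np.unique(part.labels)) == 2

    def test_single_module_complete_graph_q_zero(self):
        assert modularity_q(K4, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_three_node_path_distances_and_metrics(self):
        d = shortest_distances(PATH3).d
        np.testing.assert_allclose(d, [[0, 2, 6], [2, 0, 4], [6, 4, 0]])
        assert global_efficiency(PATH3) == pytest.approx((2 * (1 / 2 + 1 / 4 + 1 / 6)) / 6)
        assert path_length(PATH3) == pytest.approx(4.0)
        b = betweenness(PATH3)
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0])

    def test_edgeless_graph(self):
        g = wg(np.zeros((4, 4)))
        assert global_efficiency(g) == 0.0
        with pytest.raises(UndefinedMetricError):
            path_length(g)
        with pytest.raises(UndefinedMetricError):
            modularity(g)

    def test_isolated_node_infinite_distances(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        d = shortest_distances(wg(w)).d
        assert np.isinf(d[3, :3]).all() and np.isinf(d[:3, 3]).all()
        lp, n_unreach = path_length_full(wg(w))
        assert n_unreach == 6

    def test_too_small_graphs_rejected(self):
        with pytest.raises(UndefinedMetricError):
            global_efficiency(wg(np.zeros((1, 1))))
        with pytest.raises(UndefinedMetricError):
            betweenness(wg(np.zeros((2, 2))))


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("n", [5, 8, 12])
def test_all_metrics_match_bruteforce_oracles(seed, n):
    """Every weighted metric equals its independent brute-force oracle
    (Floyd-Warshall / literal-formula / exhaustive enumeration) to 1e-10."""
    g = make_graph(n, seed=1000 * n + seed, p_edge=0.45)
    w = g.w
    np.testing.assert_allclose(shortest_distances(g).d, oracles.floyd_warshall(w), atol=1e-10)
    assert global_efficiency(g) == pytest.approx(oracles.global_efficiency(w), abs=1e-10)
    assert local_efficiency(g) == pytest.approx(oracles.local_efficiency(w), abs=1e-10)
    assert assortativity(g) == pytest.approx(oracles.assortativity(w), abs=1e-10)
    assert path_length(g) == pytest.approx(oracles.path_length(w), abs=1e-10)
    np.testing.assert_allclose(clustering_per_node(g), oracles.clustering_per_node(w), atol=1e-10)
    np.testing.assert_allclose(strength(g), oracles.strength(w), atol=1e-10)
    np.testing.assert_allclose(nodal_efficiency(g), oracles.nodal_efficiency(w), atol=1e-10)
    np.testing.assert_allclose(betweenness(g), oracles.betweenness(w), atol=1e-10)
    part = modularity(g, n_restarts=5, seed=seed)
    assert part.q == pytest.approx(oracles.modularity_q(w, part.labels), abs=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_louvain_best_q_is_exhaustive_optimum_on_small_graphs(seed):
    """Seeded Louvain with restarts reaches the exhaustive-partition-search
    optimum on graphs small enough to enumerate (n <= 7)."""
    n = 5 + seed % 3
    g = make_graph(n, seed=77 + seed, p_edge=0.5)
    part = modularity(g, n_restarts=100, seed=seed)
    assert part.q == pytest.approx(oracles.exhaustive_best_q(g.w), abs=1e-10)


class TestAuc:
    def test_constant_curve_over_default_grid(self):
        d = np.round(np.arange(0.10, 0.3401, 0.01), 10)
        assert auc_over_densities(d, np.full(25, 0.4)) == pytest.approx(0.1)

    def test_single_density_uses_default_step(self):
        assert auc_over_densities([0.1], [3.0]) == pytest.approx(0.03)

    def test_linear_ramp_matches_closed_form(self):
        d = np.round(np.arange(0.10, 0.3401, 0.01), 10)
        v = np.arange(25, dtype=float)  # 0..24, sum = 300
        assert auc_over_densities(d, v) == pytest.approx(300 * 0.01)

    def test_unequal_spacing_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            auc_over_densities([0.1, 0.2, 0.4], [1, 1, 1])

    def test_trapezoid_flag(self):
        d = [0.1, 0.2, 0.3]
        assert auc_over_densities(d, [0, 1, 0], rule="trapezoid") == pytest.approx(0.1)


class TestPipelineInvariants:
    def _sweep(self, seed=2, n=14):
        g = make_graph(n, seed=seed, p_edge=1.0)
        from fconn.connectivity import ConnectivityMatrix, density_sweep

        c = ConnectivityMatrix("s", g.w, 100)
        return density_sweep(c, 0.10, 0.34, 0.06)

    def test_shapes_and_determinism(self):
        sweep = self._sweep()
        a = compute_subject_metrics(sweep, seed=4, n_restarts=5)
        b = compute_subject_metrics(sweep, seed=4, n_restarts=5)
        assert set(a.global_curves) == set(GLOBAL_METRICS)
        assert a.nodal_auc.shape == (14, 4)
        for m in GLOBAL_METRICS:
            np.testing.assert_array_equal(a.global_curves[m].values, b.global_curves[m].values)

    def test_node_relabeling_invariance(self):
        """Permuting node order leaves all global metrics unchanged."""
        g = make_graph(10, seed=31, p_edge=0.6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        gp = WeightedGraph(w=g.w[np.ix_(perm, perm)], density=g.density)
        assert global_efficiency(gp) == pytest.approx(global_efficiency(g), abs=1e-12)
        assert local_efficiency(gp) == pytest.approx(local_efficiency(g), abs=1e-12)
        assert assortativity(gp) == pytest.approx(assortativity(g), abs=1e-12)
        assert path_length(gp) == pytest.approx(path_length(g), abs=1e-12)
        assert clustering_coefficient(gp) == pytest.approx(clustering_coefficient(g), abs=1e-12)

    def test_scale_invariance_under_max_normalization(self):
        g = make_graph(10, seed=32, p_edge=0.6)
        scaled = WeightedGraph(w=3.7 * g.w, density=g.density)
        a = normalize_graph(g, "max")
        b = normalize_graph(scaled, "max")
        assert global_efficiency(b) == pytest.approx(global_efficiency(a), abs=1e-12)
        assert clustering_coefficient(b) == pytest.approx(clustering_coefficient(a), abs=1e-12)

    def test_bounds_under_max_normalization(self):
        for seed in range(5):
            g = normalize_graph(make_graph(9, seed=60 + seed, p_edge=0.5), "max")
            assert 0.0 <= global_efficiency(g) <= 1.0
            assert 0.0 <= local_efficiency(g) <= 1.0
            assert 0.0 <= clustering_coefficient(g) <= 1.0
            b = betweenness(g)
            assert (b >= 0).all() and (b <= 1).all()
            part = modularity(g, n_restarts=5, seed=seed)
            assert -0.5 <= part.q <= 1.0

    def test_eglob_monotone_and_lp_antitone_in_density(self):
        """On the nested sweep E_glob never decreases and reachable-pair L_p
        never increases as density grows."""
        sweep = self._sweep(seed=8, n=16)
        eg = [global_efficiency(g) for g in sweep]
        lp = [path_length(g) for g in sweep]
        assert all(b >= a - 1e-12 for a, b in zip(eg, eg[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(lp, lp[1:]))

    def test_inverse_lp_tracks_eglob_on_connected_graphs(self):
        """1/L_p and E_glob carry the same information up to the harmonic- vs
        arithmetic-mean distinction: strongly concordant rankings, and exactly
        equal when all pairwise distances are equal."""
        from scipy.stats import spearmanr

        gs = [make_graph(12, seed=90 + s, p_edge=0.8) for s in range(8)]
        eg = [global_efficiency(g) for g in gs]
        inv_lp = [1.0 / path_length(g) for g in gs]
        rho = spearmanr(eg, inv_lp).statistic
        assert rho >= 0.75
        # exact identity in the equidistant case
        assert 1.0 / path_length(K4) == pytest.approx(global_efficiency(K4), abs=1e-12)
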