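"""Network-based statistic: edge-wise GLM, components, permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from fconn.cohort import CohortSpec, simulate_cohort, synthetic_node_table
from fconn.connectivity import compute_fc
from fconn.inference import build_design
from fconn.nbs import (
    Component,
    EdgeStatMap,
    annotate_components,
    edgewise_stats,
    nbs_test,
    suprathreshold_components,
)


def _null_stack(n_subj, n_nodes, t_points, seed):
    """FC stack + design from a no-effect cohort."""
    spec = CohortSpec(
        n_per_group=(n_subj // 2, 0, n_subj - n_subj // 2),
        n_nodes=n_nodes, t_points=t_points, effect_map=[], seed=seed,
    )
    nodes = synthetic_node_table(n_nodes)
    subjects, series = simulate_cohort(spec, nodes)
    fcs = [compute_fc(ts) for ts in series]
    design = build_design(subjects.df, ("PD_pRBD_pos", "HC"))
    return fcs, design, nodes


class TestEdgewiseStats:
    def test_160_nodes_give_12720_tests(self):
        rng = np.random.default_rng(0)
        stack = rng.standard_normal((12, 160, 160))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in stack:
            np.fill_diagonal(s, 0)
        subs = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)],
             "group": ["PD_pRBD_pos"] * 6 + ["HC"] * 6}
        )
        design = build_design(subs, ("PD_pRBD_pos", "HC"), covariates=())
        res = edgewise_stats(stack, design)
        assert res.n_tests == 12720

    def test_200_nodes_give_19900_tests(self):
        rng = np.random.default_rng(1)
        stack = rng.standard_normal((10, 200, 200))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        subs = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)],
             "group": ["PD_pRBD_pos"] * 5 + ["HC"] * 5}
        )
        design = build_design(subs, ("PD_pRBD_pos", "HC"), covariates=())
        res = edgewise_stats(stack, design)
        assert res.n_tests == 19900

    def test_null_edge_p_values_approximately_uniform(self):
        """Kolmogorov-Smirnov sanity bound on the null edge-wise p map."""
        fcs, design, _ = _null_stack(40, 30, 166, seed=17)
        res = edgewise_stats(fcs, design)
        iu = np.triu_indices(30, 1)
        ks = sps.kstest(res.p[iu], "uniform")
        assert ks.pvalue > 0.001

    def test_matches_scalar_glm_per_edge(self):
        from fconn.inference import glm_contrast

        fcs, design, _ = _null_stack(20, 8, 60, seed=3)
        res = edgewise_stats(fcs, design)
        z = np.stack([c.z for c in fcs])
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            scalar = glm_contrast(z[:, i, j], design)
            assert res.t[i, j] == pytest.approx(scalar["t"], abs=1e-10)
            assert res.p[i, j] == pytest.approx(scalar["p"], abs=1e-10)


def _stat_map_from_edges(edges, n, t_val=-5.0):
    t = np.zeros((n, n))
    p = np.ones((n, n))
    for a, b in edges:
        t[a, b] = t[b, a] = t_val
        p[a, b] = p[b, a] = 1e-6
    return EdgeStatMap(t=t, p=p, df=30, n_tests=n * (n - 1) // 2)


class TestComponents:
    def test_no_suprathreshold_edges(self):
        res = suprathreshold_components(_stat_map_from_edges([], 6), 0.001, "negative")
        assert res == []

    def test_hand_checkable_two_components(self):
        res = suprathreshold_components(
            _stat_map_from_edges([(1, 2), (2, 3), (4, 5)], 6), 0.001, "negative"
        )
        assert [c.n_edges for c in res] == [2, 1]
        assert res[0].nodes.tolist() == [1, 2, 3]
        assert res[1].nodes.tolist() == [4, 5]

    def test_direction_filtering(self):
        m = _stat_map_from_edges([(0, 1)], 4, t_val=+5.0)
        assert suprathreshold_components(m, 0.001, "negative") == []
        assert len(suprathreshold_components(m, 0.001, "positive")) == 1
        assert len(suprathreshold_components(m, 0.001, "both")) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_union_find_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        mask = np.triu(rng.random((n, n)) < 0.08, 1)
        edges = list(zip(*np.nonzero(mask)))
        m = _stat_map_from_edges(edges, n)
        comps = suprathreshold_components(m, 0.001, "negative")
        expected = oracles.components_bfs(edges, n)
        got = [(tuple(c.nodes.tolist()), tuple(map(tuple, c.edges.tolist()))) for c in comps]
        assert got == expected

    def test_relaxing_primary_threshold_never_shrinks_components(self):
        fcs, design, _ = _null_stack(30, 20, 100, seed=5)
        res = edgewise_stats(fcs, design)
        edges_tight = {
            tuple(e)
            for c in suprathreshold_components(res, 0.01, "negative")
            for e in map(tuple, c.edges.tolist())
        }
        edges_loose = {
            tuple(e)
            for c in suprathreshold_components(res, 0.05, "negative")
            for e in map(tuple, c.edges.tolist())
        }
        assert edges_tight <= edges_loose


class TestNbsTest:
    def test_deterministic_given_seed(self):
        fcs, design, _ = _null_stack(24, 16, 80, seed=8)
        a = nbs_test(fcs, design, p_primary=0.05, n_perm=100, seed=12)
        b = nbs_test(fcs, design, p_primary=0.05, n_perm=100, seed=12)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        assert len(a.components) == len(b.components)

    def test_p_floor_is_add_one_estimator(self):
        fcs, design, _ = _null_stack(24, 16, 80, seed=9)
        res = nbs_test(fcs, design, p_primary=0.05, n_perm=100, seed=1)
        if len(res.p_values):
            assert (res.p_values >= 1 / 101 - 1e-12).all()

    def test_planted_block_effect_recovered(self):
        """A planted FC reduction across one network-block pair is recovered
        as the dominant significant component with high edge-set overlap."""
        spec = CohortSpec(
            n_per_group=(20, 0, 20), n_nodes=40, t_points=166,
            effect_map=[("PD_pRBD_pos", ("SMN", "VN"), 0.22)], seed=23,
        )
        nodes = synthetic_node_table(40)
        subjects, series = simulate_cohort(spec, nodes)
        fcs = [compute_fc(ts) for ts in series]
        design = build_design(subjects.df, ("PD_pRBD_pos", "HC"))
        res = nbs_test(fcs, design, p_primary=0.001, n_perm=200, seed=5)
        assert len(res.components) >= 1
        assert res.p_values[0] <= 2 / 201
        members = nodes.network_members()
        planted = {
            (min(a, b), max(a, b))
            for a in members["SMN"]
            for b in members["VN"]
        }
        got = {tuple(e) for e in res.components[0].edges.tolist()}
        jaccard = len(planted & got) / len(planted | got)
        assert jaccard >= 0.8

    def test_freedman_lane_and_label_permutation_agree_under_null_covariates(self):
        """With zero-effect covariates the two permutation schemes produce
        statistically indistinguishable max-component null distributions."""
        fcs, design, _ = _null_stack(30, 20, 100, seed=31)
        a = nbs_test(fcs, design, p_primary=0.01, n_perm=300, seed=3,
                     permutation="freedman_lane")
        b = nbs_test(fcs, design, p_primary=0.01, n_perm=300, seed=4,
                     permutation="labels")
        ks = sps.ks_2samp(a.null_max, b.null_max)
        assert ks.pvalue > 0.001


class TestAnnotate:
    def test_within_network_edges_count_on_diagonal(self, node_table_16):
        members = node_table_16.network_members()
        smn = members["SMN"]
        comp = Component(
            nodes=smn[:3],
            edges=np.array([(smn[0], smn[1]), (smn[0], smn[2]), (smn[1], smn[2])]),
            n_edges=3,
        )
        mat = annotate_components(comp, node_table_16)
        assert mat.loc["SMN", "SMN"] == 3
        assert mat.to_numpy().sum() == 3

    def test_conservation_cells_sum_to_edge_count(self, node_table_16):
        rng = np.random.default_rng(2)
        n = node_table_16.n_nodes
        edges = set()
        while len(edges) < 30:
            a, b = sorted(rng.choice(n, 2, replace=False))
            edges.add((int(a), int(b)))
        comp = Component(
            nodes=np.unique([v for e in edges for v in e]),
            edges=np.array(sorted(edges)),
            n_edges=len(edges),
        )
        mat = annotate_components(comp, node_table_16)
        assert mat.to_numpy().sum() == 30

    def test_planted_block_effect_lands_in_named_cell(self, node_table_16):
        members = node_table_16.network_members()
        edges = [(a, b) for a in members["SMN"][:2] for b in members["VN"][:3]]
        edges = [(min(a, b), max(a, b)) for a, b in edges]
        comp = Component(nodes=np.unique(edges), edges=np.array(sorted(edges)), n_edges=len(edges))
        mat = annotate_components(comp, node_table_16)
        off = mat.to_numpy().copy()
        np.fill_diagonal(off, 0)
        r, c = np.unravel_index(off.argmax(), off.shape)
        assert {mat.index[r], mat.columns[c]} == {"SMN", "VN"}

    def test_edge_outside_node_table_rejected(self, node_table_16):
        comp = Component(nodes=np.array([0, 99]), edges=np.array([(0, 99)]), n_edges=1)
        with pytest.raises(ValueError):
            annotate_components(comp, node_table_16)
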