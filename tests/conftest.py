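import numpy as np
import pytest

from fconn.cohort import CohortSpec, simulate_cohort, synthetic_node_table
from fconn.connectivity import WeightedGraph


@pytest.fixture(scope="session")
def node_table_16():
    return synthetic_node_table(16)


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-group cohort shared by inference-level tests."""
    spec = CohortSpec(n_per_group=(10, 10, 12), n_nodes=24, t_points=100, seed=42)
    nodes = synthetic_node_table(24)
    subjects, series = simulate_cohort(spec, nodes)
    return spec, nodes, subjects, series


def make_graph(n: int, seed: int, p_edge: float = 0.5) -> WeightedGraph:
    from oracles import random_weighted_graph

    rng = np.random.default_rng(seed)
    w = random_weighted_graph(n, rng, p_edge)
    iu = np.triu_indices(n, 1)
    density = np.count_nonzero(w[iu]) / iu[0].size
    return WeightedGraph(w=w, density=density)


@pytest.fixture(scope="session")
def node_table_48():
    """48 nodes: every one of the eight networks has at least 2 ROIs."""
    return synthetic_node_table(48)
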