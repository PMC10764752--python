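"""Network-based statistic: edge-wise GLM, suprathreshold components, and the
max-component permutation test.

Cluster-style inference on graphs: every ROI-pair edge gets a covariate-
adjusted t statistic; edges passing a primary threshold (two-tailed p below
``p_primary``, sign matching the tested direction) are grouped into connected
components, and each observed component's edge count is referred to a
permutation null distribution of the MAXIMUM component edge count.

With nuisance covariates the null is built by Freedman-Lane residual
permutation (permute the reduced-model residuals, add back the nuisance fit,
re-fit the full model); naive row permutation of the responses is available
via ``permutation='labels'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix
from .inference import Design
from .io import NodeTable, NETWORKS

logger = logging.getLogger("fconn")


@dataclass
class EdgeStatMap:
    """Symmetric edge-wise t and p matrices for one contrast."""

    t: np.ndarray
    p: np.ndarray
    df: int
    n_tests: int


@dataclass
class Component:
    """A maximal connected set of suprathreshold edges."""

    nodes: np.ndarray
    edges: np.ndarray  # (m, 2) node pairs, i < j
    n_edges: int


@dataclass
class NBSResult:
    components: list[Component]
    p_values: np.ndarray
    null_max: np.ndarray
    n_permutations: int
    direction: str
    p_primary: float
    seed: int
    stats: EdgeStatMap


def _stack_to_edges(z_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subj, N, N) stack -> (n_subj, n_edges) upper-triangle matrix plus
    the (i, j) index arrays."""
    n = z_stack.shape[1]
    iu, ju = np.triu_indices(n, 1)
    return z_stack[:, iu, ju], iu, ju


def _fit_t(y: np.ndarray, x: np.ndarray, xtx_inv: np.ndarray, group_col: int) -> np.ndarray:
    """Vectorized OLS t statistics for the group column across response
    columns of y (n_subjects x n_responses)."""
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[group_col, group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[group_col] / se
    t[~np.isfinite(t)] = 0.0
    return t


def edgewise_stats(
    fc_stack: list[ConnectivityMatrix] | np.ndarray, design: Design
) -> EdgeStatMap:
    """GLM contrast applied independently to every upper-triangle edge of the
    FC stack (n*(n-1)/2 tests)."""
    if isinstance(fc_stack, list):
        z_stack = np.stack([c.z for c in fc_stack])
    else:
        z_stack = np.asarray(fc_stack, dtype=float)
    if z_stack.shape[0] != design.x.shape[0]:
        raise ValueError(
            f"{z_stack.shape[0]} FC matrices for {design.x.shape[0]} design rows"
        )
    y, iu, ju = _stack_to_edges(z_stack)
    x = design.x
    xtx_inv = np.linalg.inv(x.T @ x)
    tvec = _fit_t(y, x, xtx_inv, design.group_col)
    df = design.df_resid
    pvec = 2.0 * stats.t.sf(np.abs(tvec), df)
    n = z_stack.shape[1]
    tm = np.zeros((n, n))
    pm = np.ones((n, n))
    tm[iu, ju] = tvec
    pm[iu, ju] = pvec
    tm = tm + tm.T
    pm = np.minimum(pm, pm.T)
    np.fill_diagonal(pm, 1.0)
    return EdgeStatMap(t=tm, p=pm, df=df, n_tests=iu.size)


class _UnionFind:
    """Array union-find with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=int)

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _edge_mask(stats_map: EdgeStatMap, p_primary: float, direction: str) -> np.ndarray:
    t, p = stats_map.t, stats_map.p
    if direction == "negative":
        sign_ok = t < 0
    elif direction == "positive":
        sign_ok = t > 0
    elif direction == "both":
        sign_ok = np.ones_like(t, dtype=bool)
    else:
        raise ValueError("direction must be 'negative', 'positive' or 'both'")
    return (p < p_primary) & sign_ok


def _components_from_edges(edges_i: np.ndarray, edges_j: np.ndarray, n: int) -> list[Component]:
    uf = _UnionFind(n)
    for a, b in zip(edges_i, edges_j):
        uf.union(int(a), int(b))
    roots: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(edges_i, edges_j):
        roots.setdefault(uf.find(int(a)), []).append((int(a), int(b)))
    comps = [
        Component(
            nodes=np.unique(np.array(es).ravel()),
            edges=np.array(sorted(es)),
            n_edges=len(es),
        )
        for es in roots.values()
    ]
    comps.sort(key=lambda c: (-c.n_edges, int(c.nodes[0])))
    return comps


def suprathreshold_components(
    stats_map: EdgeStatMap, p_primary: float = 0.001, direction: str = "negative"
) -> list[Component]:
    """Connected components of the graph of edges passing the primary
    threshold with the requested sign, sorted by edge count (descending),
    deterministically."""
    mask = np.triu(_edge_mask(stats_map, p_primary, direction), 1)
    ei, ej = np.nonzero(mask)
    if ei.size == 0:
        return []
    return _components_from_edges(ei, ej, stats_map.t.shape[0])


def _max_component_size(tvec, pvec, iu, ju, n, direction) -> int:
    if direction == "negative":
        keep = pvec & (tvec < 0)
    elif direction == "positive":
        keep = pvec & (tvec > 0)
    else:
        keep = pvec
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return 0
    uf = _UnionFind(n)
    ei, ej = iu[idx], ju[idx]
    for a, b in zip(ei, ej):
        uf.union(int(a), int(b))
    roots = np.array([uf.find(int(a)) for a in ei])
    _, counts = np.unique(roots, return_counts=True)
    return int(counts.max())


def nbs_test(
    fc_stack: list[ConnectivityMatrix] | np.ndarray,
    design: Design,
    p_primary: float = 0.001,
    n_perm: int = 5000,
    direction: str = "negative",
    seed: int = 0,
    permutation: str = "freedman_lane",
) -> NBSResult:
    """The network-based statistic permutation test.

    Component p = (1 + #{null max >= observed edge count}) / (n_perm + 1)
    (the add-one estimator; p can never be 0).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives a granular p-value floor of %.3f", n_perm, 1 / (n_perm + 1))
    if permutation not in ("freedman_lane", "labels"):
        raise ValueError("permutation must be 'freedman_lane' or 'labels'")
    if isinstance(fc_stack, list):
        z_stack = np.stack([c.z for c in fc_stack])
    else:
        z_stack = np.asarray(fc_stack, dtype=float)
    observed = edgewise_stats(z_stack, design)
    components = suprathreshold_components(observed, p_primary, direction)

    y, iu, ju = _stack_to_edges(z_stack)
    x = design.x
    n_subj, n = z_stack.shape[0], z_stack.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    df = design.df_resid
    # critical |t| for the primary threshold: cheaper than p per permutation
    t_crit = stats.t.isf(p_primary / 2.0, df)

    if permutation == "freedman_lane":
        z_nuis = np.delete(x, design.group_col, axis=1)
        gamma = np.linalg.lstsq(z_nuis, y, rcond=None)[0]
        fitted = z_nuis @ gamma
        resid = y - fitted
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n_subj)
        if permutation == "freedman_lane":
            y_b = fitted + resid[perm]
        else:
            y_b = y[perm]
        t_b = _fit_t(y_b, x, xtx_inv, design.group_col)
        null_max[b] = _max_component_size(
            t_b, np.abs(t_b) > t_crit, iu, ju, n, direction
        )
    p_values = np.array(
        [(1 + int((null_max >= c.n_edges).sum())) / (n_perm + 1) for c in components]
    )
    return NBSResult(
        components=components,
        p_values=p_values,
        null_max=null_max,
        n_permutations=n_perm,
        direction=direction,
        p_primary=p_primary,
        seed=seed,
        stats=observed,
    )


def annotate_components(
    component: Component, nodes: NodeTable
) -> pd.DataFrame:
    """8x8 matrix counting a component's edges by the network membership of
    their endpoints; each edge lands in the canonical (network-order) cell so
    the cells always sum to the component edge count."""
    labels = nodes.networks
    order = {net: k for k, net in enumerate(NETWORKS)}
    mat = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS))
    for a, b in component.edges:
        if a >= len(labels) or b >= len(labels):
            raise ValueError(f"edge ({a}, {b}) outside the node table")
        na, nb = sorted((labels[a], labels[b]), key=order.get)
        mat.loc[na, nb] += 1
    return mat


def component_edge_table(
    result: NBSResult, component: Component, nodes: NodeTable
) -> pd.DataFrame:
    """Tidy edge list for one component: node_i, node_j, t, network_i, network_j."""
    labels = nodes.networks
    rows = [
        {
            "node_i": int(a), "node_j": int(b),
            "t": result.stats.t[a, b],
            "network_i": labels[a], "network_j": labels[b],
        }
        for a, b in component.edges
    ]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "t", "network_i", "network_j"])
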