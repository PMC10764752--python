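"""Weighted graph topology: efficiency, path length, clustering, assortativity,
modularity, strength, betweenness, nodal efficiency, and AUC aggregation.

Conventions fixed across the package:

* weight -> length mapping for shortest paths is ``l_ij = 1/w_ij`` (the
  standard connectome convention);
* weights may be max-normalized (divided by the graph's maximum weight)
  before metric computation, which bounds efficiency and clustering in
  [0, 1] even though Fisher-z weights can exceed 1 — the pipeline default;
* the neighborhood degree ``k_i`` in denominators ``k_i (k_i - 1)`` is the
  BINARY neighbor count (the formula is not otherwise well-defined), while
  the reported nodal "degree" is the weighted strength — the two are
  computed and labelled distinctly;
* characteristic path length on a disconnected graph averages over reachable
  ordered pairs only, with the unreachable count reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import louvain_communities
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import WeightedGraph

logger = logging.getLogger("fconn")

GLOBAL_METRICS = ("E_glob", "E_loc", "assortativity", "modularity", "L_p", "C_p")
NODAL_METRICS = ("strength", "betweenness", "nodal_efficiency", "clustering")


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this graph."""


@dataclass
class DistanceMatrix:
    """All-pairs shortest weighted path lengths; unreachable pairs infinite."""

    d: np.ndarray


@dataclass
class Partition:
    """Module assignment per node and its modularity quality Q."""

    labels: np.ndarray
    q: float


@dataclass
class MetricCurve:
    """One global metric across the density sweep, with its AUC."""

    name: str
    densities: np.ndarray
    values: np.ndarray
    auc: float


def normalize_graph(g: WeightedGraph, mode: str = "max") -> WeightedGraph:
    """Divide all weights by the graph maximum (``mode='max'``) or pass
    through unchanged (``mode='none'``)."""
    if mode == "none":
        return g
    if mode != "max":
        raise ValueError("normalize mode must be 'max' or 'none'")
    wmax = g.w.max()
    if wmax == 0:
        return g
    return WeightedGraph(w=g.w / wmax, density=g.density)


def _length_matrix(w: np.ndarray) -> csr_matrix:
    i, j = np.nonzero(np.triu(w, 1))
    lengths = 1.0 / w[i, j]
    n = w.shape[0]
    m = csr_matrix((np.concatenate([lengths, lengths]),
                    (np.concatenate([i, j]), np.concatenate([j, i]))),
                   shape=(n, n))
    return m


def shortest_distances(g: WeightedGraph | np.ndarray) -> DistanceMatrix:
    """Dijkstra from every source on edge lengths 1/w; unreachable = inf."""
    w = g.w if isinstance(g, WeightedGraph) else np.asarray(g, dtype=float)
    if w.shape[0] == 0:
        return DistanceMatrix(d=np.zeros((0, 0)))
    d = shortest_path(_length_matrix(w), method="D", directed=False)
    return DistanceMatrix(d=d)


def _as_w(g) -> np.ndarray:
    return g.w if isinstance(g, WeightedGraph) else np.asarray(g, dtype=float)


def nodal_efficiency(g, dist: DistanceMatrix | None = None) -> np.ndarray:
    """E_i = mean over other nodes of 1/d_ij, with 1/inf := 0."""
    w = _as_w(g)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("nodal efficiency needs at least 2 nodes")
    d = dist.d if dist is not None else shortest_distances(g).d
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(g, dist: DistanceMatrix | None = None) -> float:
    """Mean over nodes of nodal efficiency: how efficiently the whole network
    exchanges information."""
    return float(nodal_efficiency(g, dist).mean())


def local_efficiency(g) -> float:
    """Mean over nodes of the weighted local efficiency of each node's
    neighborhood subgraph.

    Per-node term: sum over ordered neighbor pairs (j, h) of
    (w_ij * w_ih / d_jh(N_i))^(1/3), divided by k_i (k_i - 1), where
    d_jh(N_i) is the shortest path between j and h through neighbors of i
    only, and k_i the binary neighbor count; nodes with k_i < 2 contribute 0.
    """
    w = _as_w(g)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("local efficiency needs at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d_sub = shortest_path(_length_matrix(sub), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d_sub
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        wi = w[i, nbrs]
        terms = np.cbrt(np.outer(wi, wi) * inv)
        total += terms.sum() / (k * (k - 1))
    return total / n


def strength(g) -> np.ndarray:
    """Weighted degree: sum of link weights at each node."""
    return _as_w(g).sum(axis=1)


def assortativity(g) -> float:
    """Weighted assortativity: weight-weighted Pearson correlation of the
    strengths at the two ends of each link.  Raises when the weighted
    strength variance over link end-points is zero (e.g. regular graphs)."""
    w = _as_w(g)
    i, j = np.nonzero(np.triu(w, 1))
    if i.size < 2:
        raise UndefinedMetricError("assortativity needs at least 2 links")
    wij = w[i, j]
    l = wij.sum()
    k = strength(g)
    ki, kj = k[i], k[j]
    mean_end = (wij * 0.5 * (ki + kj)).sum() / l
    num = (wij * ki * kj).sum() / l - mean_end**2
    den = (wij * 0.5 * (ki**2 + kj**2)).sum() / l - mean_end**2
    if den <= 1e-15:
        raise UndefinedMetricError(
            "assortativity undefined: zero variance of link end-point strengths"
        )
    return float(num / den)


def modularity_q(g, labels: np.ndarray) -> float:
    """Newman weighted modularity of a given partition:
    Q = (1/l) * sum_ij [w_ij - k_i k_j / l] delta(m_i, m_j), with the sum over
    ordered node pairs and l the total weight over ordered pairs."""
    w = _as_w(g)
    l2 = w.sum()
    if l2 == 0:
        raise UndefinedMetricError("modularity undefined for an edgeless graph")
    k = w.sum(axis=1)
    labels = np.asarray(labels)
    q = 0.0
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        q += w[np.ix_(idx, idx)].sum() - (k[idx].sum() ** 2) / l2
    return float(q / l2)


def modularity(g, n_restarts: int = 20, seed: int = 0) -> Partition:
    """Best-Q partition over ``n_restarts`` seeded Louvain runs.

    Q is evaluated by :func:`modularity_q`; the restart achieving the maximum
    is kept, ties resolved toward the earliest restart (deterministic)."""
    w = _as_w(g)
    if w.sum() == 0:
        raise UndefinedMetricError("modularity undefined for an edgeless graph")
    gx = nx.from_numpy_array(w)
    best: Partition | None = None
    for r in range(n_restarts):
        comms = louvain_communities(gx, weight="weight", seed=seed * 100003 + r)
        labels = np.empty(w.shape[0], dtype=int)
        for m, nodes in enumerate(comms):
            labels[list(nodes)] = m
        q = modularity_q(g, labels)
        if best is None or q > best.q + 1e-15:
            best = Partition(labels=labels, q=q)
    return best


def path_length_full(g, dist: DistanceMatrix | None = None) -> tuple[float, int]:
    """Characteristic path length over REACHABLE ordered pairs, plus the
    number of unreachable ordered pairs."""
    w = _as_w(g)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("path length needs at least 2 nodes")
    d = dist.d if dist is not None else shortest_distances(g).d
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    reach = np.isfinite(vals)
    n_unreach = int((~reach).sum())
    if not reach.any():
        raise UndefinedMetricError("path length undefined: no reachable pairs")
    return float(vals[reach].mean()), n_unreach


def path_length(g, dist: DistanceMatrix | None = None) -> float:
    return path_length_full(g, dist)[0]


def clustering_per_node(g) -> np.ndarray:
    """Weighted clustering C_i = 2 t_i / (k_i (k_i - 1)) with triangle
    intensity t_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3); C_i = 0 if k_i < 2."""
    w = _as_w(g)
    w3 = np.cbrt(w)
    two_t = np.einsum("ij,jh,hi->i", w3, w3, w3)  # = 2 t_i (ordered pairs)
    k = (w > 0).sum(axis=1)
    c = np.zeros(w.shape[0])
    mask = k >= 2
    c[mask] = two_t[mask] / (k[mask] * (k[mask] - 1.0))
    return c


def clustering_coefficient(g) -> float:
    """Network clustering: mean of per-node weighted clustering."""
    w = _as_w(g)
    if w.shape[0] == 0:
        raise UndefinedMetricError("clustering needs at least 1 node")
    return float(clustering_per_node(g).mean())


def betweenness(g) -> np.ndarray:
    """Shortest-path betweenness with lengths 1/w, Brandes accumulation,
    normalized by (n-1)(n-2) over ordered source-target pairs (b_i in [0,1])."""
    w = _as_w(g)
    n = w.shape[0]
    if n < 3:
        raise UndefinedMetricError("betweenness needs at least 3 nodes")
    gx = nx.Graph()
    gx.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(w, 1))
    gx.add_weighted_edges_from(
        ((int(a), int(b), 1.0 / w[a, b]) for a, b in zip(i, j)), weight="length"
    )
    bc = nx.betweenness_centrality(gx, weight="length", normalized=True)
    return np.array([bc[v] for v in range(n)])


def nodal_metrics(g, dist: DistanceMatrix | None = None) -> pd.DataFrame:
    """The four per-node measures: strength, betweenness, nodal efficiency,
    clustering — one row per node."""
    return pd.DataFrame(
        {
            "strength": strength(g),
            "betweenness": betweenness(g),
            "nodal_efficiency": nodal_efficiency(g, dist),
            "clustering": clustering_per_node(g),
        }
    )


def auc_over_densities(
    densities: np.ndarray,
    values: np.ndarray,
    rule: str = "rectangle",
    default_step: float = 0.01,
) -> float:
    """Area under a metric-vs-density curve on a UNIFORM grid.

    Rectangle rule (sum of value * step, the neuroimaging-toolbox
    convention) by default; ``rule='trapezoid'`` available.  A single-point
    curve uses ``default_step``.  Raises on unequal spacing.
    """
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.size != values.size or densities.size == 0:
        raise ValueError("densities and values must be equal-length and nonempty")
    if densities.size == 1:
        step = default_step
    else:
        diffs = np.diff(densities)
        if (diffs <= 0).any():
            raise ValueError("densities must be strictly increasing")
        step = float(diffs[0])
        if not np.allclose(diffs, step, rtol=0, atol=1e-9):
            raise ValueError("density grid must be uniformly spaced")
    if rule == "rectangle":
        return float(values.sum() * step)
    if rule == "trapezoid":
        return float(np.trapezoid(values, dx=step))
    raise ValueError("rule must be 'rectangle' or 'trapezoid'")


@dataclass
class SubjectMetrics:
    """All global curves and nodal surfaces for one subject's density sweep."""

    subject_id: str
    densities: np.ndarray
    global_curves: dict[str, MetricCurve]
    nodal_values: dict[str, np.ndarray]  # metric -> (n_densities, n_nodes)
    nodal_auc: pd.DataFrame  # node x metric

    def global_auc(self) -> dict[str, float]:
        return {name: c.auc for name, c in self.global_curves.items()}


def compute_subject_metrics(
    sweep: list[WeightedGraph],
    subject_id: str = "sub",
    seed: int = 0,
    n_restarts: int = 20,
    normalize: str = "max",
    auc_rule: str = "rectangle",
) -> SubjectMetrics:
    """Evaluate the six global and four nodal measures at every density of a
    sweep, and aggregate each curve by its AUC.

    Weights are max-normalized per graph by default so efficiency and
    clustering stay in [0, 1].  Deterministic given ``seed`` (modularity
    restarts are seeded per density).
    """
    if not sweep:
        raise ValueError("empty density sweep")
    densities = np.array([g.density for g in sweep])
    n_nodes = sweep[0].n
    glob: dict[str, list[float]] = {m: [] for m in GLOBAL_METRICS}
    nodal: dict[str, list[np.ndarray]] = {m: [] for m in NODAL_METRICS}
    for di, g_raw in enumerate(sweep):
        g = normalize_graph(g_raw, normalize)
        dist = shortest_distances(g)
        glob["E_glob"].append(global_efficiency(g, dist))
        glob["E_loc"].append(local_efficiency(g))
        try:
            glob["assortativity"].append(assortativity(g))
        except UndefinedMetricError:
            logger.warning("assortativity undefined at density %.2f", g.density)
            glob["assortativity"].append(np.nan)
        glob["modularity"].append(modularity(g, n_restarts, seed=seed * 1009 + di).q)
        glob["L_p"].append(path_length(g, dist))
        glob["C_p"].append(clustering_coefficient(g))
        tbl = nodal_metrics(g, dist)
        for m in NODAL_METRICS:
            nodal[m].append(tbl[m].to_numpy())
    curves = {
        m: MetricCurve(
            name=m,
            densities=densities,
            values=np.array(v),
            auc=auc_over_densities(densities, np.array(v), rule=auc_rule),
        )
        for m, v in glob.items()
    }
    nodal_arr = {m: np.vstack(v) for m, v in nodal.items()}
    nodal_auc = pd.DataFrame(
        {
            m: [
                auc_over_densities(densities, nodal_arr[m][:, i], rule=auc_rule)
                for i in range(n_nodes)
            ]
            for m in NODAL_METRICS
        }
    )
    nodal_auc.index.name = "node_id"
    return SubjectMetrics(
        subject_id=subject_id,
        densities=densities,
        global_curves=curves,
        nodal_values=nodal_arr,
        nodal_auc=nodal_auc,
    )


def metrics_long_table(sm: SubjectMetrics) -> pd.DataFrame:
    """Tidy per-density table: subject_id, metric, density, value."""
    rows = []
    for name, c in sm.global_curves.items():
        for d, v in zip(c.densities, c.values):
            rows.append((sm.subject_id, name, d, v))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "density", "value"])
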