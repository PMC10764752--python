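"""Independent brute-force oracles used only by the tests.

Every function here recomputes a quantity from its definition by the slowest,
most literal route available (triple loops, exhaustive enumeration), entirely
independently of the package's implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on edge lengths 1/w, by Floyd-Warshall."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    d = floyd_warshall(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = floyd_warshall(w)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d_sub = floyd_warshall(sub)
        s = 0.0
        for aj, j in enumerate(nbrs):
            for ah, h in enumerate(nbrs):
                if j == h or not np.isfinite(d_sub[aj, ah]) or d_sub[aj, ah] == 0:
                    continue
                s += (w[i, j] * w[i, h] / d_sub[aj, ah]) ** (1.0 / 3.0)
        total += s / (k * (k - 1))
    return total / n


def strength(w: np.ndarray) -> np.ndarray:
    return w.sum(axis=1)


def assortativity(w: np.ndarray) -> float:
    """Literal term-by-term evaluation over the link set."""
    n = w.shape[0]
    links = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
    k = strength(w)
    l = sum(w[i, j] for i, j in links)
    s_kk = sum(w[i, j] * k[i] * k[j] for i, j in links) / l
    s_mean = sum(w[i, j] * 0.5 * (k[i] + k[j]) for i, j in links) / l
    s_sq = sum(w[i, j] * 0.5 * (k[i] ** 2 + k[j] ** 2) for i, j in links) / l
    return (s_kk - s_mean**2) / (s_sq - s_mean**2)


def modularity_q(w: np.ndarray, labels) -> float:
    """Literal double loop over ordered node pairs."""
    n = w.shape[0]
    l = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / l
    return q / l


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def exhaustive_best_q(w: np.ndarray) -> float:
    """Maximum modularity over every partition of the node set."""
    n = w.shape[0]
    best = -np.inf
    for part in set_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for m, block in enumerate(part):
            labels[block] = m
        best = max(best, modularity_q(w, labels))
    return best


def path_length(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    vals = [
        d[i, j]
        for i in range(w.shape[0])
        for j in range(w.shape[0])
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals))


def clustering_per_node(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        t *= 0.5
        out[i] = 2.0 * t / (k * (k - 1))
    return out


def betweenness(w: np.ndarray) -> np.ndarray:
    """Brandes-free betweenness: shortest-path counts via distance-ordered DP
    on the Floyd-Warshall metric, normalized over ordered pairs by
    (n-1)(n-2)."""
    n = w.shape[0]
    d = floyd_warshall(w)
    tol = 1e-12
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            for u in range(n):
                if u != v and w[u, v] > 0 and np.isfinite(d[s, u]):
                    if abs(d[s, u] + 1.0 / w[u, v] - d[s, v]) < tol:
                        sigma[s, v] += sigma[s, u]
    b = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(n):
                if len({i, s, t}) < 3 or not np.isfinite(d[s, t]):
                    continue
                if abs(d[s, i] + d[i, t] - d[s, t]) < tol and sigma[s, t] > 0:
                    b[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return b / ((n - 1) * (n - 2))


def bh_from_definition(p: np.ndarray, q: float):
    """Benjamini-Hochberg step-up straight from the definition, plus the
    monotone adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= q * k / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    adj = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, ranked[k - 1] * m / k)
        adj[order[k - 1]] = running
    return reject, adj


def pooled_t(y: np.ndarray, is_group1: np.ndarray) -> float:
    """Classical pooled-variance two-sample t statistic (group1 minus group0)."""
    a, b = y[is_group1], y[~is_group1]
    n1, n2 = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(x.T @ x, x.T @ y)


def residualize_then_correlate(x, y, cov):
    """Two-stage regression oracle for the partial correlation."""
    n = len(x)
    z = np.column_stack([np.ones(n), cov])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def components_bfs(edges, n):
    """Connected components of an edge set by breadth-first search."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    comps = []
    for nodes in nx.connected_components(g):
        es = sorted(
            (min(a, b), max(a, b)) for a, b in g.edges(nodes)
        )
        comps.append((tuple(sorted(nodes)), tuple(es)))
    comps.sort(key=lambda c: (-len(c[1]), c[0][0]))
    return comps


def random_weighted_graph(n: int, rng: np.random.Generator, p_edge: float = 0.5) -> np.ndarray:
    """Random connected-ish weighted graph with continuous weights in (0.2, 1.2)."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.2, 1.2)
    # guarantee at least a spanning path so most metrics are defined
    perm = rng.permutation(n)
    for a, b in zip(perm[:-1], perm[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.uniform(0.2, 1.2)
    return w
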