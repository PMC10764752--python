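"""Connectivity matrices and density-thresholded weighted graphs.

Functional connectivity is the Pearson correlation of each ROI pair's time
series, Fisher r-to-z transformed.  Proportional (density) thresholding keeps
the strongest positive d% of possible edges with their weights, so every
subject's graph has the same edge count; negative correlations are discarded
by default (shortest-path metrics are undefined for negative lengths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import TimeSeriesMatrix, ValidationError

logger = logging.getLogger("fconn")

#: |r| clip bound applied before the r-to-z transform to keep z finite.
R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z FC matrix for one subject, zero diagonal."""

    subject_id: str
    z: np.ndarray
    n_timepoints: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.isfinite(z).all():
            raise ValidationError("connectivity matrix contains non-finite values")
        if not np.allclose(z, z.T):
            raise ValidationError("connectivity matrix must be symmetric")
        self.z = z

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class WeightedGraph:
    """Nonnegative weighted adjacency after proportional thresholding."""

    w: np.ndarray
    density: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("adjacency must be square")
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        if np.diag(w).any():
            raise ValidationError("diagonal must be zero")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n, 1)
        return int(np.count_nonzero(self.w[iu]))

    def edge_list(self) -> np.ndarray:
        """(i, j) pairs of present edges, i < j, lexicographic order."""
        i, j = np.nonzero(np.triu(self.w, 1))
        return np.column_stack([i, j])


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation of all node pairs, Fisher r-to-z transformed.

    r is clipped to |r| <= 1 - 1e-7 before atanh so duplicated columns give a
    large finite z; the diagonal is set to 0.  Raises on constant columns.
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 time points for correlation")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(
            f"zero-variance time series at node(s) {dead.tolist()} "
            f"for subject {ts.subject_id}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z, n_timepoints=x.shape[0])


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def threshold_by_density(
    c: ConnectivityMatrix | np.ndarray,
    density: float,
    negative_edges: str = "discard",
) -> WeightedGraph:
    """Keep the round(density * n(n-1)/2) strongest positive edges, weighted.

    Negative z entries are discarded first (or folded in by absolute value
    with ``negative_edges='absolute'``).  Ties at the cutoff are broken by
    (smaller i, smaller j) lexicographic edge order, making the result
    bit-reproducible.  If fewer positive edges exist than requested all are
    kept and a warning logs the achieved density.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if negative_edges not in ("discard", "absolute"):
        raise ValueError("negative_edges must be 'discard' or 'absolute'")
    z = c.z if isinstance(c, ConnectivityMatrix) else np.asarray(c, dtype=float)
    n = z.shape[0]
    if negative_edges == "absolute":
        z = np.abs(z)
    iu, ju = np.triu_indices(n, 1)
    wvals = z[iu, ju]
    pos = wvals > 0
    n_possible = n * (n - 1) // 2
    k = _round_half_even(density * n_possible)
    order = np.lexsort((ju, iu, -wvals))  # weight desc, then (i, j) asc
    order = order[pos[order]]
    if order.size < k:
        logger.warning(
            "only %d positive edges available for requested %d (achieved density %.4f)",
            order.size, k, order.size / n_possible if n_possible else 0.0,
        )
        keep = order
    else:
        keep = order[:k]
    w = np.zeros_like(z)
    w[iu[keep], ju[keep]] = wvals[keep]
    w = w + w.T
    return WeightedGraph(w=w, density=density)


def density_grid(d_min: float = 0.10, d_max: float = 0.34, step: float = 0.01) -> np.ndarray:
    """Inclusive density grid by integer stepping (no floating-point drift)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if d_min > d_max:
        raise ValueError(f"d_min={d_min} exceeds d_max={d_max}")
    n_steps = int(round((d_max - d_min) / step))
    if abs(d_min + n_steps * step - d_max) > 1e-9:
        n_steps = int(np.floor((d_max - d_min) / step + 1e-9))
    return np.array([round(d_min + k * step, 10) for k in range(n_steps + 1)])


def density_sweep(
    c: ConnectivityMatrix,
    d_min: float = 0.10,
    d_max: float = 0.34,
    step: float = 0.01,
    negative_edges: str = "discard",
) -> list[WeightedGraph]:
    """One thresholded graph per density on the inclusive grid (default
    10%..34% in 1% steps: 25 graphs).  Edge sets are nested across the sweep."""
    return [
        threshold_by_density(c, d, negative_edges=negative_edges)
        for d in density_grid(d_min, d_max, step)
    ]


def write_fc_matrix(c: ConnectivityMatrix, path) -> None:
    np.savetxt(path, c.z, delimiter="\t", fmt="%.10g")


def read_fc_matrix(path, subject_id: str | None = None) -> ConnectivityMatrix:
    z = np.loadtxt(path, delimiter="\t")
    from pathlib import Path as _P

    return ConnectivityMatrix(
        subject_id=subject_id or _P(path).stem, z=z, n_timepoints=0
    )


def write_edge_list(g: WeightedGraph, path) -> None:
    """Weighted edge list as TSV: node_i, node_j, weight."""
    edges = g.edge_list()
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\t{g.w[i, j]:.10g}\n")
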