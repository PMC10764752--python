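"""Domain tables and file I/O: node/subject tables, ROI time series, QC, group assignment.

All on-disk formats are tab-separated text with a header row.  Internally node
indices are 0-based and contiguous; file headers may carry arbitrary ROI labels
which are mapped once at read time.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fconn")

#: The eight large-scale networks of the 160-ROI functional parcellation.
NETWORKS = ("VN", "SMN", "DAN", "VAN", "SCN", "FPN", "DMN", "CBN")

#: ROI count per network in the packaged 160-node fixture.
NETWORK_SIZES = {
    "CBN": 18, "DMN": 33, "FPN": 21, "SCN": 7,
    "VAN": 16, "DAN": 14, "SMN": 29, "VN": 22,
}

GROUPS = ("PD_pRBD_pos", "PD_pRBD_neg", "HC")

CLINICAL_COLUMNS = (
    "moca", "rbdqhk_total", "rbdqhk_subscale", "hamd",
    "updrs3", "hy_stage", "duration_years",
)

_NODE_COLUMNS = ("node_id", "label", "x_mm", "y_mm", "z_mm", "network", "sphere_radius_mm")
_QC_COLUMNS = ("mean_fd", "max_translation", "max_rotation", "brain_coverage")


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """A table violates a domain invariant."""


@dataclass
class NodeTable:
    """ROI table: one row per node, with MNI coordinates and network label."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _NODE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"node table missing column(s): {', '.join(missing)}")
        ids = self.df["node_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate node_id values in node table")
        if len(ids) and not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValidationError("node_id values must be contiguous from 0")
        bad = sorted(set(self.df["network"]) - set(NETWORKS))
        if bad:
            raise ValidationError(
                f"unknown network label(s) {bad}; allowed: {list(NETWORKS)}"
            )
        self.df = self.df.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.df)

    @property
    def networks(self) -> np.ndarray:
        """Per-node network label, aligned to node_id order."""
        return self.df["network"].to_numpy()

    def network_members(self) -> dict[str, np.ndarray]:
        """Node indices per network, in the canonical eight-network order."""
        labels = self.networks
        return {net: np.flatnonzero(labels == net) for net in NETWORKS}


@dataclass
class SubjectTable:
    """Per-subject covariates, QC metrics and clinical scores."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject_id", "group"):
            if col not in self.df.columns:
                raise FormatError(f"subject table missing column: {col}")
        sids = self.df["subject_id"]
        if sids.duplicated().any():
            raise ValidationError("duplicate subject_id values")
        bad = sorted(set(self.df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group label(s) {bad}; allowed: {list(GROUPS)}")
        if "mean_fd" in self.df.columns and (self.df["mean_fd"] < 0).any():
            raise ValidationError("mean_fd must be non-negative")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.df)


@dataclass
class TimeSeriesMatrix:
    """Preprocessed BOLD time series for one subject: T time points x N nodes."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time series must be a 2-D T x N matrix")
        if not np.isfinite(self.data).all():
            raise ValidationError(f"time series for {self.subject_id} contains non-finite values")
        if self.node_ids is None:
            self.node_ids = np.arange(self.data.shape[1])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def read_node_table(path: str | Path) -> NodeTable:
    """Read a tab-separated node table and validate it."""
    df = pd.read_csv(path, sep="\t")
    return NodeTable(df)


def write_node_table(nodes: NodeTable, path: str | Path) -> None:
    nodes.df.to_csv(path, sep="\t", index=False)


def packaged_node_table() -> NodeTable:
    """The packaged 160-node, eight-network fixture.

    Network memberships follow the published eight-network grouping of the
    160-ROI functional parcellation (CBN 18, DMN 33, FPN 21, SCN 7, VAN 16,
    DAN 14, SMN 29, VN 22).  Coordinates are synthetic placeholders in
    MNI-plausible ranges, not the atlas coordinates.
    """
    ref = importlib.resources.files("fconn.data") / "nodes160_synthetic.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_node_table(p)


def read_subject_table(path: str | Path) -> SubjectTable:
    """Read a tab-separated subject table and validate it."""
    df = pd.read_csv(path, sep="\t")
    return SubjectTable(df)


def write_subject_table(subjects: SubjectTable, path: str | Path) -> None:
    subjects.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeseries(
    path: str | Path,
    node_table: NodeTable | None = None,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
) -> TimeSeriesMatrix:
    """Read a T x N time-series matrix (TSV, headerless or with node labels).

    If a header naming the nodes is present and a node table is given, columns
    are reordered to node-table order.  Raises a shape error when the column
    count does not match the node table.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split("\t")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens)
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.vectorize(lambda v: not _numeric(str(v)))(arr.astype(str))
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"non-numeric token at row {r}, column {c} of {path.name}")
    if node_table is not None:
        if arr.shape[1] != node_table.n_nodes:
            raise FormatError(
                f"time-series has {arr.shape[1]} columns but node table has "
                f"{node_table.n_nodes} nodes"
            )
        if has_header:
            labels = list(node_table.df["label"])
            cols = list(df.columns.astype(str))
            if set(cols) == set(labels):
                df = df[labels]
                arr = df.to_numpy()
    if arr.shape[0] < 30:
        logger.warning("time series %s has only %d time points", path.name, arr.shape[0])
    return TimeSeriesMatrix(
        subject_id=subject_id or path.stem, data=arr, tr_seconds=tr_seconds
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.8g")


def apply_qc(
    subjects: SubjectTable,
    max_trans_mm: float = 2.0,
    max_rot_deg: float = 2.0,
    max_mean_fd_mm: float = 0.2,
    min_coverage: float = 0.90,
) -> SubjectTable:
    """Flag subjects failing motion/coverage quality control.

    A subject is excluded iff a motion metric STRICTLY exceeds its threshold
    or brain coverage falls strictly below the minimum; boundary values are
    retained.  Sets/overwrites ``qc_pass``; idempotent.
    """
    df = subjects.df.copy()
    missing = [c for c in _QC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing QC column(s): {', '.join(missing)}")
    reasons = {
        "max_translation": df["max_translation"] > max_trans_mm,
        "max_rotation": df["max_rotation"] > max_rot_deg,
        "mean_fd": df["mean_fd"] > max_mean_fd_mm,
        "brain_coverage": df["brain_coverage"] < min_coverage,
    }
    excluded = np.zeros(len(df), dtype=bool)
    for name, mask in reasons.items():
        m = mask.to_numpy()
        if m.any():
            logger.info("QC: %d subject(s) excluded for %s", int(m.sum()), name)
        excluded |= m
    df["qc_pass"] = ~excluded
    return SubjectTable(df)


def classify_prbd(rbdqhk_total: float, rbdqhk_subscale: float) -> str:
    """Probable-RBD assignment from the RBDQ-HK questionnaire.

    PD_pRBD_pos iff total >= 19 and subscale >= 8; PD_pRBD_neg iff total < 19
    and subscale < 8; the two mixed quadrants are 'excluded'.
    """
    if rbdqhk_total < 0 or rbdqhk_subscale < 0:
        raise ValidationError("RBDQ-HK scores must be non-negative")
    if rbdqhk_total >= 19 and rbdqhk_subscale >= 8:
        return "PD_pRBD_pos"
    if rbdqhk_total < 19 and rbdqhk_subscale < 8:
        return "PD_pRBD_neg"
    return "excluded"
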