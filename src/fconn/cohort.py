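"""Synthetic resting-state cohort generator.

Draws per-subject ROI time series from zero-mean multivariate normals whose
correlation matrices carry an eight-network block structure, together with
demographic covariates, head-motion QC metrics and clinical scores whose
group-level layout mirrors an early-PD study design: two patient groups split
by probable REM-sleep-behaviour-disorder (pRBD) status plus healthy controls.

Group FC differences are injected as additive correlation reductions on whole
network-block pairs.  One master seed spawns per-subject child seeds by a
fixed rule (spawn_key = (group_index, subject_index)), so enlarging a cohort
never changes already-generated subjects.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    GROUPS,
    NETWORK_SIZES,
    NETWORKS,
    NodeTable,
    SubjectTable,
    TimeSeriesMatrix,
    write_node_table,
    write_subject_table,
    write_timeseries,
)

logger = logging.getLogger("fconn")


class ConfigurationError(ValueError):
    """A cohort specification cannot produce a valid correlation model."""


#: Per-group moments for the continuous covariates (mean, sd) and male fraction.
DEFAULT_COVARIATE_MODEL = {
    "PD_pRBD_pos": {"age": (61.2, 6.5), "education": (11.0, 3.7), "mean_fd": (0.10, 0.04), "male_fraction": 0.528},
    "PD_pRBD_neg": {"age": (58.4, 8.8), "education": (9.0, 4.4), "mean_fd": (0.10, 0.04), "male_fraction": 0.456},
    "HC": {"age": (60.5, 8.3), "education": (12.0, 4.4), "mean_fd": (0.09, 0.04), "male_fraction": 0.451},
}

#: Per-group clinical-score moments; None marks a score not collected for HC.
DEFAULT_CLINICAL_MODEL = {
    "PD_pRBD_pos": {
        "moca": (24.0, 2.7), "rbdqhk_total": (28.5, 8.0), "rbdqhk_subscale": (14.0, 4.0),
        "hamd": (8.0, 5.0), "updrs3": (24.5, 12.0), "hy_stage": None, "duration_years": (3.0, 2.0),
    },
    "PD_pRBD_neg": {
        "moca": (26.0, 3.0), "rbdqhk_total": (3.5, 4.0), "rbdqhk_subscale": (2.0, 2.0),
        "hamd": (4.0, 3.0), "updrs3": (23.0, 11.0), "hy_stage": None, "duration_years": (2.0, 1.8),
    },
    "HC": {
        "moca": (26.0, 3.0), "rbdqhk_total": (7.0, 5.0), "rbdqhk_subscale": (3.0, 2.5),
        "hamd": (1.0, 2.0), "updrs3": None, "hy_stage": None, "duration_years": None,
    },
}

#: Block-level FC reductions: (group, (network_a, network_b), delta_rho).
#: Patients with pRBD lose FC in posterior blocks (sensorimotor, visual,
#: default-mode); patients without pRBD in frontoparietal/ventral-attention.
DEFAULT_EFFECT_MAP = [
    ("PD_pRBD_pos", ("SMN", "SMN"), 0.08),
    ("PD_pRBD_pos", ("VN", "VN"), 0.08),
    ("PD_pRBD_pos", ("DMN", "DMN"), 0.08),
    ("PD_pRBD_pos", ("SMN", "VN"), 0.05),
    ("PD_pRBD_pos", ("SMN", "DMN"), 0.05),
    ("PD_pRBD_pos", ("VN", "DMN"), 0.05),
    ("PD_pRBD_neg", ("FPN", "FPN"), 0.06),
    ("PD_pRBD_neg", ("VAN", "VAN"), 0.06),
    ("PD_pRBD_neg", ("FPN", "VAN"), 0.04),
]


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic study cohort.

    ``n_per_group`` orders the groups (PD_pRBD_pos, PD_pRBD_neg, HC).  The
    default sizes, covariate and clinical moments follow the study layout the
    generator emulates; ``effect_map`` lists additive correlation reductions
    applied to whole network-block pairs of the named group.
    """

    n_per_group: tuple[int, int, int] = (36, 57, 71)
    n_nodes: int = 160
    t_points: int = 166
    tr_seconds: float = 2.0
    rho_within: float = 0.35
    rho_between: float = 0.10
    effect_map: list[tuple[str, tuple[str, str], float]] = field(
        default_factory=lambda: [tuple_e for tuple_e in DEFAULT_EFFECT_MAP]
    )
    covariate_model: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATE_MODEL.items()})
    clinical_model: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CLINICAL_MODEL.items()})
    noise_sd: float = 0.0
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.rho_within, self.rho_between):
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"baseline correlation {rho} outside (-1, 1)")
        for group, pair, _ in self.effect_map:
            if group not in GROUPS:
                raise ConfigurationError(f"effect_map group {group!r} not in {list(GROUPS)}")
            for net in pair:
                if net not in NETWORKS:
                    raise ConfigurationError(f"effect_map network {net!r} not in {list(NETWORKS)}")


def synthetic_node_table(n_nodes: int = 160, seed: int = 12345) -> NodeTable:
    """Build a synthetic node table with the eight-network block layout.

    For ``n_nodes == 160`` the per-network counts are the published ones
    (CBN 18, DMN 33, FPN 21, SCN 7, VAN 16, DAN 14, SMN 29, VN 22); for other
    sizes counts are allocated proportionally (largest remainder, every
    network keeps at least one node when possible).  Coordinates are drawn
    from MNI-plausible per-network boxes and are synthetic placeholders.
    """
    if n_nodes < len(NETWORKS):
        counts = {net: (1 if i < n_nodes else 0) for i, net in enumerate(NETWORKS)}
    elif n_nodes == 160:
        counts = dict(NETWORK_SIZES)
    else:
        total = sum(NETWORK_SIZES.values())
        quotas = {net: n_nodes * NETWORK_SIZES[net] / total for net in NETWORKS}
        counts = {net: int(np.floor(q)) for net, q in quotas.items()}
        remainders = sorted(NETWORKS, key=lambda n: quotas[n] - counts[n], reverse=True)
        for net in remainders[: n_nodes - sum(counts.values())]:
            counts[net] += 1
    boxes = {  # rough MNI bounding boxes per system, mm
        "VN": ((-40, 40), (-100, -60), (-15, 20)),
        "SMN": ((-60, 60), (-40, 0), (20, 70)),
        "DAN": ((-50, 50), (-70, -30), (30, 60)),
        "VAN": ((-60, 60), (-20, 25), (-5, 50)),
        "SCN": ((-30, 30), (-25, 10), (-5, 15)),
        "FPN": ((-50, 50), (-10, 50), (20, 55)),
        "DMN": ((-55, 55), (-75, 60), (-10, 50)),
        "CBN": ((-40, 40), (-85, -45), (-45, -15)),
    }
    rng = np.random.default_rng(seed)
    rows = []
    node_id = 0
    for net in NETWORKS:
        (x0, x1), (y0, y1), (z0, z1) = boxes[net]
        for k in range(counts[net]):
            rows.append(
                {
                    "node_id": node_id,
                    "label": f"{net}_{k:02d}",
                    "x_mm": round(float(rng.uniform(x0, x1)), 1),
                    "y_mm": round(float(rng.uniform(y0, y1)), 1),
                    "z_mm": round(float(rng.uniform(z0, z1)), 1),
                    "network": net,
                    "sphere_radius_mm": 5.0,
                }
            )
            node_id += 1
    return NodeTable(pd.DataFrame(rows))


def build_target_covariance(
    spec: CohortSpec, group: str, node_table: NodeTable
) -> np.ndarray:
    """Target correlation matrix for one group: two-level block structure
    (rho_within inside network blocks, rho_between across) minus the
    effect-map reductions for that group; unit diagonal, positive definite
    (diagonal loading applied and logged if required)."""
    labels = node_table.networks
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    c = np.where(same, spec.rho_within, spec.rho_between).astype(float)
    for eff_group, (net_a, net_b), delta in spec.effect_map:
        if eff_group != group:
            continue
        in_a = labels == net_a
        in_b = labels == net_b
        block = np.outer(in_a, in_b) | np.outer(in_b, in_a)
        c[block] -= delta
    np.fill_diagonal(c, 1.0)
    off = c[~np.eye(n, dtype=bool)]
    if off.size and (off.min() <= -1.0 or off.max() >= 1.0):
        raise ConfigurationError(
            f"target correlation for {group} leaves (-1, 1): range "
            f"[{off.min():.3f}, {off.max():.3f}]"
        )
    min_eig = float(np.linalg.eigvalsh(c).min()) if n else 1.0
    if min_eig <= 1e-10:
        load = abs(min_eig) + 1e-6
        if load > 0.1:
            raise ConfigurationError(
                f"target correlation for {group} is far from positive definite "
                f"(min eigenvalue {min_eig:.4f})"
            )
        c = (c + load * np.eye(n)) / (1.0 + load)
        logger.info("diagonal loading %.2e applied to %s target correlation", load, group)
    return c


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    """Fixed child-seed rule: spawn_key identifies the subject, not the cohort size."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def simulate_subject(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    node_table: NodeTable,
    subject_id: str = "sub",
    target: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Draw one subject's T x N time series from the group's target correlation.

    Gaussian stationary signal via Cholesky; optional AR(1) temporal
    autocorrelation (``ar_coeff``) and additive white noise (``noise_sd``).
    Deterministic given the generator state.
    """
    if spec.t_points < spec.n_nodes / 2:
        logger.warning(
            "t_points=%d < n_nodes/2=%.0f: correlation estimates will be unstable",
            spec.t_points, spec.n_nodes / 2,
        )
    if target is None:
        target = build_target_covariance(spec, group, node_table)
    chol = np.linalg.cholesky(target)
    innov = rng.standard_normal((spec.t_points, target.shape[0]))
    if spec.ar_coeff:
        phi = spec.ar_coeff
        scale = np.sqrt(1.0 - phi**2)
        for t in range(1, spec.t_points):
            innov[t] = phi * innov[t - 1] + scale * innov[t]
    data = innov @ chol.T
    if spec.noise_sd:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    return TimeSeriesMatrix(
        subject_id=subject_id, data=data, tr_seconds=spec.tr_seconds
    )


def _draw_truncated(rng, mean, sd, lo=None, hi=None):
    x = rng.normal(mean, sd)
    if lo is not None:
        x = max(lo, x)
    if hi is not None:
        x = min(hi, x)
    return x


def _draw_clinical(rng: np.random.Generator, group: str, model: dict) -> dict:
    """Clinical scores consistent with the group label: RBDQ-HK draws respect
    the questionnaire cut-offs (total >= 19 and subscale >= 8 for pRBD-positive
    patients, both strictly below for pRBD-negative) so the classification rule
    recovers the generator's labels."""
    m = model[group]
    out: dict[str, float] = {}

    def moments(key):
        return m.get(key)

    for key in ("moca", "hamd", "updrs3", "duration_years"):
        mm = moments(key)
        if mm is None:
            out[key] = np.nan
            continue
        lo = 0.1 if key == "duration_years" else 0.0
        hi = 30.0 if key == "moca" else None
        val = _draw_truncated(rng, *mm, lo=lo, hi=hi)
        out[key] = round(val, 1) if key == "duration_years" else float(round(val))
    # H&Y stage: early-disease categorical draw for patients only
    if group == "HC":
        out["hy_stage"] = np.nan
    else:
        probs = (0.2, 0.75, 0.05) if group == "PD_pRBD_pos" else (0.4, 0.55, 0.05)
        out["hy_stage"] = float(rng.choice([1.0, 2.0, 2.5], p=probs))
    tot_m = moments("rbdqhk_total")
    sub_m = moments("rbdqhk_subscale")
    if group == "PD_pRBD_pos":
        out["rbdqhk_total"] = float(round(_draw_truncated(rng, *tot_m, lo=19, hi=100)))
        out["rbdqhk_subscale"] = float(round(_draw_truncated(rng, *sub_m, lo=8, hi=70)))
    elif group == "PD_pRBD_neg":
        out["rbdqhk_total"] = float(round(_draw_truncated(rng, *tot_m, lo=0, hi=18)))
        out["rbdqhk_subscale"] = float(round(_draw_truncated(rng, *sub_m, lo=0, hi=7)))
    else:
        out["rbdqhk_total"] = float(round(_draw_truncated(rng, *tot_m, lo=0, hi=18)))
        out["rbdqhk_subscale"] = float(round(_draw_truncated(rng, *sub_m, lo=0, hi=7)))
    return out


def _draw_covariates(rng: np.random.Generator, group: str, model: dict) -> dict:
    m = model[group]
    return {
        "age": round(_draw_truncated(rng, *m["age"], lo=30.0), 1),
        "sex": int(rng.random() < m["male_fraction"]),
        "education": float(round(_draw_truncated(rng, *m["education"], lo=0.0))),
        "mean_fd": round(_draw_truncated(rng, *m["mean_fd"], lo=0.01, hi=0.2), 4),
        "max_translation": round(_draw_truncated(rng, 0.6, 0.4, lo=0.02, hi=2.0), 3),
        "max_rotation": round(_draw_truncated(rng, 0.5, 0.35, lo=0.02, hi=2.0), 3),
        "brain_coverage": round(_draw_truncated(rng, 0.97, 0.015, lo=0.9, hi=1.0), 4),
    }


def simulate_cohort(
    spec: CohortSpec, node_table: NodeTable | None = None
) -> tuple[SubjectTable, list[TimeSeriesMatrix]]:
    """Generate the full cohort: subject table plus one time series per subject."""
    if node_table is None:
        node_table = synthetic_node_table(spec.n_nodes)
    if node_table.n_nodes != spec.n_nodes:
        raise ConfigurationError(
            f"node table has {node_table.n_nodes} nodes, spec requests {spec.n_nodes}"
        )
    targets = {g: build_target_covariance(spec, g, node_table) for g in GROUPS}
    rows = []
    series: list[TimeSeriesMatrix] = []
    for gi, (group, n_g) in enumerate(zip(GROUPS, spec.n_per_group)):
        for si in range(n_g):
            rng = _subject_rng(spec.seed, gi, si)
            sid = f"{group}_{si:03d}"
            row = {"subject_id": sid, "group": group}
            row.update(_draw_covariates(rng, group, spec.covariate_model))
            row.update(_draw_clinical(rng, group, spec.clinical_model))
            rows.append(row)
            series.append(
                simulate_subject(spec, group, rng, node_table, sid, targets[group])
            )
    columns = [
        "subject_id", "group", "age", "sex", "education", "mean_fd",
        "max_translation", "max_rotation", "brain_coverage",
        "moca", "rbdqhk_total", "rbdqhk_subscale", "hamd", "updrs3",
        "hy_stage", "duration_years",
    ]
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return SubjectTable(df), series


def spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["n_per_group"] = list(spec.n_per_group)
    d["effect_map"] = [
        {"group": g, "networks": list(pair), "delta_rho": float(delta)}
        for g, pair, delta in spec.effect_map
    ]
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if "n_per_group" in d:
        d["n_per_group"] = tuple(d["n_per_group"])
    if "effect_map" in d and d["effect_map"] and isinstance(d["effect_map"][0], dict):
        d["effect_map"] = [
            (e["group"], tuple(e["networks"]), float(e["delta_rho"]))
            for e in d["effect_map"]
        ]
    return CohortSpec(**d)


def save_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    node_table: NodeTable | None = None,
) -> Path:
    """Simulate and write a cohort directory: subjects.tsv, nodes.tsv,
    timeseries/<subject_id>.tsv and the resolved spec.yaml for provenance."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    if node_table is None:
        node_table = synthetic_node_table(spec.n_nodes)
    subjects, series = simulate_cohort(spec, node_table)
    write_node_table(node_table, out / "nodes.tsv")
    write_subject_table(subjects, out / "subjects.tsv")
    for ts in series:
        write_timeseries(ts, out / "timeseries" / f"{ts.subject_id}.tsv")
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)
    return out
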