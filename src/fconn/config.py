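"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import CohortSpec, spec_from_dict, spec_to_dict

DEFAULT_CONTRASTS = (
    "PD_pRBD_pos-vs-HC",
    "PD_pRBD_neg-vs-HC",
    "PD_pRBD_pos-vs-PD_pRBD_neg",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    cohort_dir: str = "cohort"
    out_dir: str = "results"
    d_min: float = 0.10
    d_max: float = 0.34
    d_step: float = 0.01
    negative_edges: str = "discard"  # or "absolute"
    normalize_weights: str = "max"  # or "none"
    auc_rule: str = "rectangle"  # or "trapezoid"
    p_primary: float = 0.001
    n_perm: int = 5000
    fdr_q: float = 0.05
    nbs_permutation: str = "freedman_lane"  # or "labels"
    modularity_restarts: int = 20
    contrasts: list[str] = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "education", "mean_fd"])
    seed: int = 0
    simulate: CohortSpec | None = None

    def __post_init__(self) -> None:
        if self.d_max < self.d_min:
            raise ConfigError(f"d_max={self.d_max} < d_min={self.d_min}")
        if self.d_step <= 0:
            raise ConfigError("d_step must be positive")
        if not 0 < self.p_primary < 1:
            raise ConfigError("p_primary must be in (0, 1)")
        for c in self.contrasts:
            parse_contrast(c)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = spec_to_dict(self.simulate)
        return d

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def parse_contrast(spec: str) -> tuple[str, str]:
    """'GROUPA-vs-GROUPB' -> (GROUPA, GROUPB); GROUPB is the reference."""
    parts = spec.split("-vs-")
    if len(parts) != 2 or not all(parts):
        raise ConfigError(f"contrast must be 'GROUPA-vs-GROUPB', got {spec!r}")
    return parts[0], parts[1]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        raw["simulate"] = spec_from_dict(raw["simulate"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
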