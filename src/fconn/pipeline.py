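"""End-to-end pipeline stages over a cohort directory.

Each stage reads the cohort (and earlier stage outputs where natural), writes
tidy TSV/JSON under the output directory, and is deterministic under the
configured seed.  ``run_all`` sequences simulate (optional) -> fc -> metrics
-> compare -> nbs -> netfc and writes a provenance file (config hash, seed,
package versions) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import save_cohort
from .config import RunConfig, parse_contrast
from .connectivity import ConnectivityMatrix, compute_fc, density_sweep, write_fc_matrix, read_fc_matrix
from .inference import Design, build_design, compare_metrics, correlation_screen
from .io import (
    CLINICAL_COLUMNS,
    NodeTable,
    SubjectTable,
    read_node_table,
    read_subject_table,
    read_timeseries,
)
from .metrics import compute_subject_metrics, GLOBAL_METRICS, NODAL_METRICS
from .nbs import annotate_components, component_edge_table, nbs_test
from .netfc import compare_network_fc, network_fc_table

logger = logging.getLogger("fconn")

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_cohort(cohort_dir: str | Path) -> tuple[NodeTable, SubjectTable, list]:
    """Read nodes.tsv, subjects.tsv and timeseries/<subject_id>.tsv."""
    d = Path(cohort_dir)
    nodes = read_node_table(d / "nodes.tsv")
    subjects = read_subject_table(d / "subjects.tsv")
    series = [
        read_timeseries(d / "timeseries" / f"{sid}.tsv", nodes, subject_id=sid)
        for sid in subjects.df["subject_id"]
    ]
    return nodes, subjects, series


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_fc(cfg: RunConfig) -> list[ConnectivityMatrix]:
    """Fisher-z FC matrix per subject, written under <out>/fc/."""
    nodes, subjects, series = load_cohort(cfg.cohort_dir)
    out = Path(cfg.out_dir) / "fc"
    out.mkdir(parents=True, exist_ok=True)
    fcs = []
    for ts in series:
        c = compute_fc(ts)
        write_fc_matrix(c, out / f"{c.subject_id}.tsv")
        fcs.append(c)
    return fcs


def _load_fc(cfg: RunConfig, subjects: SubjectTable) -> list[ConnectivityMatrix]:
    out = Path(cfg.out_dir) / "fc"
    if out.is_dir() and all(
        (out / f"{sid}.tsv").exists() for sid in subjects.df["subject_id"]
    ):
        return [read_fc_matrix(out / f"{sid}.tsv", sid) for sid in subjects.df["subject_id"]]
    _, _, series = load_cohort(cfg.cohort_dir)
    return [compute_fc(ts) for ts in series]


def run_metrics(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Density-sweep graph metrics with AUC per subject.

    Writes global_auc.tsv (subject x metric), nodal_auc.tsv (tidy:
    subject, node, metric, auc) and metrics_by_density.tsv (tidy curves).
    """
    nodes, subjects, _ = load_cohort(cfg.cohort_dir)
    fcs = _load_fc(cfg, subjects)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    glob_rows, nodal_rows, tidy = [], [], []
    for k, c in enumerate(fcs):
        sweep = density_sweep(c, cfg.d_min, cfg.d_max, cfg.d_step, cfg.negative_edges)
        sm = compute_subject_metrics(
            sweep,
            subject_id=c.subject_id,
            seed=cfg.seed * 131 + k,
            n_restarts=cfg.modularity_restarts,
            normalize=cfg.normalize_weights,
            auc_rule=cfg.auc_rule,
        )
        glob_rows.append({"subject_id": c.subject_id, **sm.global_auc()})
        na = sm.nodal_auc.reset_index().melt(
            id_vars="node_id", var_name="metric", value_name="auc"
        )
        na.insert(0, "subject_id", c.subject_id)
        nodal_rows.append(na)
        for name, curve in sm.global_curves.items():
            for d, v in zip(curve.densities, curve.values):
                tidy.append((c.subject_id, name, d, v))
    global_auc = pd.DataFrame(glob_rows)
    nodal_auc = pd.concat(nodal_rows, ignore_index=True)
    _write(global_auc, out / "global_auc.tsv")
    _write(nodal_auc, out / "nodal_auc.tsv")
    _write(
        pd.DataFrame(tidy, columns=["subject_id", "metric", "density", "value"]),
        out / "metrics_by_density.tsv",
    )
    return global_auc, nodal_auc


def _design_for(cfg: RunConfig, subjects: SubjectTable, contrast: str) -> Design:
    return build_design(
        subjects.df, parse_contrast(contrast), tuple(cfg.covariates)
    )


def run_compare(cfg: RunConfig) -> dict[str, dict[str, pd.DataFrame]]:
    """Covariate-adjusted contrasts of global and nodal AUC metrics, plus the
    clinical correlation screen for metrics showing group differences."""
    out = Path(cfg.out_dir)
    nodes, subjects, _ = load_cohort(cfg.cohort_dir)
    try:
        global_auc = pd.read_csv(out / "global_auc.tsv", sep="\t")
        nodal_auc = pd.read_csv(out / "nodal_auc.tsv", sep="\t")
    except FileNotFoundError as exc:
        raise StageError("compare", f"metrics outputs missing: {exc}") from exc
    global_auc = global_auc.set_index("subject_id")
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for contrast in cfg.contrasts:
        design = _design_for(cfg, subjects, contrast)
        gvals = global_auc.loc[design.subject_ids, list(GLOBAL_METRICS)]
        gres = compare_metrics(gvals, design, q=cfg.fdr_q, fdr=False)
        _write(gres, out / f"global_compare_{contrast}.tsv")
        nres_all = []
        for metric in NODAL_METRICS:
            wide = (
                nodal_auc[nodal_auc["metric"] == metric]
                .pivot(index="subject_id", columns="node_id", values="auc")
                .loc[design.subject_ids]
            )
            nres = compare_metrics(wide, design, q=cfg.fdr_q, fdr=True)
            nres.insert(0, "metric", metric)
            nres = nres.rename(columns={"name": "node_id"})
            nres_all.append(nres)
        nodal_res = pd.concat(nres_all, ignore_index=True)
        _write(nodal_res, out / f"nodal_compare_{contrast}.tsv")
        results[contrast] = {"global": gres, "nodal": nodal_res}
    # correlation screen: global metrics with an uncorrected group difference,
    # against clinical scores, within each patient group
    candidates = sorted(
        {
            r["name"]
            for res in results.values()
            for r in res["global"].to_dict("records")
            if r["p"] < 0.05
        }
    )
    clinical_cols = [c for c in CLINICAL_COLUMNS if c in subjects.df.columns]
    screen = correlation_screen(
        global_auc.reset_index().set_index("subject_id")[candidates]
        .reindex(subjects.df["subject_id"]),
        subjects.df.set_index("subject_id")[clinical_cols]
        .reindex(subjects.df["subject_id"]),
        subjects.df.set_index("subject_id")[list(cfg.covariates)]
        .reindex(subjects.df["subject_id"]),
        subjects.df.set_index("subject_id")["group"].reindex(subjects.df["subject_id"]),
        ["PD_pRBD_pos", "PD_pRBD_neg"],
        q=cfg.fdr_q,
    )
    _write(screen, out / "correlation_screen.tsv")
    results["correlation_screen"] = {"screen": screen}
    return results


def run_nbs(cfg: RunConfig) -> dict[str, dict]:
    """NBS per contrast; decreases and increases are tested as separate
    one-sided families at the two-tailed primary threshold."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes, subjects, _ = load_cohort(cfg.cohort_dir)
    fcs = _load_fc(cfg, subjects)
    fc_by_id = {c.subject_id: c for c in fcs}
    summary_rows = []
    results: dict[str, dict] = {}
    for contrast in cfg.contrasts:
        design = _design_for(cfg, subjects, contrast)
        stack = [fc_by_id[sid] for sid in design.subject_ids]
        for direction in ("negative", "positive"):
            res = nbs_test(
                stack,
                design,
                p_primary=cfg.p_primary,
                n_perm=cfg.n_perm,
                direction=direction,
                seed=cfg.seed * 977 + zlib.crc32(f"{contrast}|{direction}".encode()) % 100000,
                permutation=cfg.nbs_permutation,
            )
            tag = f"{contrast}_{direction}"
            results[tag] = {"result": res}
            np.savetxt(
                out / f"nbs_null_{tag}.tsv", res.null_max, fmt="%d", header="max_edges", comments=""
            )
            for ci, (comp, pval) in enumerate(zip(res.components, res.p_values)):
                summary_rows.append(
                    {
                        "contrast": contrast, "direction": direction, "component": ci,
                        "n_nodes": len(comp.nodes), "n_edges": comp.n_edges,
                        "p": pval, "significant": pval < 0.05,
                    }
                )
                if pval < 0.05:
                    _write(
                        component_edge_table(res, comp, nodes),
                        out / f"nbs_edges_{tag}_c{ci}.tsv",
                    )
                    _write(
                        annotate_components(comp, nodes),
                        out / f"nbs_networks_{tag}_c{ci}.tsv",
                        index=True,
                    )
    summary = pd.DataFrame(
        summary_rows,
        columns=["contrast", "direction", "component", "n_nodes", "n_edges", "p", "significant"],
    )
    _write(summary, out / "nbs_summary.tsv")
    results["summary"] = summary
    return results


def run_netfc(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Large-scale within/between-network FC table and its group contrasts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes, subjects, _ = load_cohort(cfg.cohort_dir)
    fcs = _load_fc(cfg, subjects)
    table = network_fc_table(fcs, nodes)
    _write(table.rename_axis("subject_id").reset_index(), out / "network_fc.tsv")
    results = {"table": table}
    for contrast in cfg.contrasts:
        design = _design_for(cfg, subjects, contrast)
        res = compare_network_fc(table.loc[design.subject_ids], design, q=cfg.fdr_q)
        _write(res, out / f"network_fc_compare_{contrast}.tsv")
        results[contrast] = res
    return results


def write_provenance(cfg: RunConfig) -> Path:
    import networkx
    import scipy
    import statsmodels

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "versions": {
            "fconn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    path = out / "provenance.json"
    path.write_text(json.dumps(prov, indent=2, sort_keys=True, default=str) + "\n")
    return path


def run_all(cfg: RunConfig) -> Path:
    """Run every stage on a cohort directory (simulating it first when the
    config carries a cohort spec and the directory does not exist)."""
    stages: list[tuple[str, callable]] = []
    if cfg.simulate is not None and not (Path(cfg.cohort_dir) / "subjects.tsv").exists():
        stages.append(("simulate", lambda: save_cohort(cfg.simulate, cfg.cohort_dir)))
    stages += [
        ("fc", lambda: run_fc(cfg)),
        ("metrics", lambda: run_metrics(cfg)),
        ("compare", lambda: run_compare(cfg)),
        ("nbs", lambda: run_nbs(cfg)),
        ("netfc", lambda: run_netfc(cfg)),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
    write_provenance(cfg)
    return Path(cfg.out_dir)
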