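"""Covariate-adjusted group inference: GLM contrasts on AUC metrics, BH-FDR,
effect sizes, and partial correlations with clinical scores.

Effect-size conventions: three are always reported because published values
labelled "Cohen's d" in this literature often track t^2/df (Cohen's f^2)
rather than the classical definition —

* classical Cohen's d  = t * sqrt(1/n1 + 1/n2)
* partial eta-squared  = t^2 / (t^2 + df)
* Cohen's f^2          = t^2 / df       (for correlations: r^2 / (1 - r^2))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")


class DesignError(ValueError):
    """The design matrix is unusable (rank deficiency, missing values)."""


@dataclass
class Design:
    """GLM design: intercept, 0/1 group contrast and nuisance covariates.

    The contrast column codes membership of ``group_a`` as 1 against the
    reference ``group_b`` as 0; only subjects of the two groups enter.
    """

    x: np.ndarray
    columns: list[str]
    group_col: int
    n1: int  # subjects coded 1 (group_a)
    n2: int  # subjects coded 0 (reference)
    subject_ids: list[str]

    @property
    def df_resid(self) -> int:
        return self.x.shape[0] - self.x.shape[1]


def build_design(
    subjects: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> Design:
    """Assemble the design matrix for ``group_a`` vs ``group_b`` (reference).

    Requires complete covariate values; raises naming collinear columns when
    the design is rank deficient.
    """
    group_a, group_b = contrast
    sel = subjects[subjects["group"].isin([group_a, group_b])]
    if (sel["group"] == group_a).sum() < 2 or (sel["group"] == group_b).sum() < 2:
        raise DesignError(f"need >= 2 subjects per group for {group_a} vs {group_b}")
    cols = {"intercept": np.ones(len(sel)), "group": (sel["group"] == group_a).to_numpy(float)}
    for c in covariates:
        if c not in sel.columns:
            raise DesignError(f"missing covariate column: {c}")
        v = sel[c].to_numpy(float)
        if np.isnan(v).any():
            raise DesignError(f"covariate {c} has missing values")
        cols[c] = v
    x = np.column_stack(list(cols.values()))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = list(cols)
        # name the offending columns: those whose removal restores full rank
        collinear = [
            names[k]
            for k in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, k, axis=1)) == rank
        ]
        raise DesignError(f"rank-deficient design; collinear column(s): {collinear}")
    return Design(
        x=x,
        columns=list(cols),
        group_col=1,
        n1=int(cols["group"].sum()),
        n2=int(len(sel) - cols["group"].sum()),
        subject_ids=list(sel["subject_id"]),
    )


def effect_sizes(t: float, n1: int, n2: int, df: int) -> tuple[float, float]:
    """Classical Cohen's d and partial eta-squared from a contrast t."""
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    eta = t**2 / (t**2 + df) if df > 0 else np.nan
    return float(d), float(eta)


def glm_contrast(y: np.ndarray, design: Design, name: str = "") -> dict:
    """OLS fit of y on the design; t, two-tailed p and effect sizes for the
    group column."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.x.shape[0]:
        raise DesignError(
            f"response has {y.shape[0]} rows, design has {design.x.shape[0]}"
        )
    if np.isnan(y).any():
        raise DesignError("response contains missing values")
    x = design.x
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = design.df_resid
    sigma2 = resid @ resid / df
    y_scale = max(1.0, float(np.abs(y).max()))
    if sigma2 <= (1e-12 * y_scale) ** 2:
        sigma2 = 0.0  # numerically zero residual variance
    se = np.sqrt(sigma2 * xtx_inv[design.group_col, design.group_col])
    est = beta[design.group_col]
    if abs(est) <= 1e-12 * y_scale:
        est = 0.0
    if se > 0:
        t = est / se
    else:
        # zero residual variance: identical groups give t = 0, a nonzero
        # contrast with no noise is infinitely significant
        t = 0.0 if abs(est) < 1e-12 else np.inf * np.sign(est)
    p = 2.0 * stats.t.sf(abs(t), df)
    d, eta = effect_sizes(t, design.n1, design.n2, df)
    return {
        "name": name,
        "estimate": float(beta[design.group_col]),
        "t": float(t),
        "p": float(p),
        "cohens_d": d,
        "partial_eta_sq": eta,
        "cohens_f2": float(t**2 / df) if df > 0 else np.nan,
        "df": df,
        "n1": design.n1,
        "n2": design.n2,
    }


def fdr_bh(p_values, q: float = 0.05, method: str = "fdr_bh") -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR (Benjamini-Yekutieli via
    ``method='fdr_by'``): returns (rejections, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1] with no missing entries")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError("method must be 'fdr_bh' or 'fdr_by'")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=method)
    return reject, p_adj


def compare_metrics(
    values: pd.DataFrame, design: Design, q: float = 0.05, fdr: bool = True
) -> pd.DataFrame:
    """GLM contrast for each column of a subject x metric table, optionally
    BH-FDR corrected across columns (the nodal-metric convention)."""
    rows = []
    for col in values.columns:
        rows.append(glm_contrast(values[col].to_numpy(), design, name=str(col)))
    out = pd.DataFrame(rows)
    if fdr and len(out):
        reject, p_adj = fdr_bh(out["p"].to_numpy(), q)
        out["p_fdr"] = p_adj
        out["significant"] = reject
    return out


def partial_correlation(
    x, y, covariates=None
) -> tuple[float, float, int]:
    """Pearson correlation of the two covariate-residualized variables.

    Pairwise-complete filtering first; df = n - n_covariates - 2.  Returns
    (r, two-tailed p, n complete cases used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    n = int(mask.sum())
    n_cov = cov.shape[1]
    if n < n_cov + 3:
        raise ValueError(
            f"insufficient complete cases: {n} available, {n_cov + 3} required"
        )
    xm, ym, cm = x[mask], y[mask], cov[mask]
    z = np.column_stack([np.ones(n), cm])
    rx = xm - z @ np.linalg.lstsq(z, xm, rcond=None)[0]
    ry = ym - z @ np.linalg.lstsq(z, ym, rcond=None)[0]
    tol = 1e-10
    if rx.std() <= tol * max(1.0, np.abs(xm).max()) or ry.std() <= tol * max(1.0, np.abs(ym).max()):
        raise ValueError("partial correlation undefined: a residualized variable is constant")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - n_cov - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def correlation_screen(
    metric_values: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series,
    which_groups: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations of each candidate metric with each clinical score
    within each requested group, BH-FDR corrected across the whole screen.

    Missing clinical values are dropped pairwise-complete; the n used per
    correlation is reported.  Effect size is Cohen's f^2 = r^2/(1-r^2).
    """
    rows = []
    for grp in which_groups:
        in_g = (groups == grp).to_numpy()
        for metric in metric_values.columns:
            for score in clinical.columns:
                try:
                    r, p, n = partial_correlation(
                        metric_values.loc[in_g, metric],
                        clinical.loc[in_g, score],
                        covariates.loc[in_g].to_numpy(float),
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "group": grp, "metric": metric, "clinical": score,
                        "r": r, "p": p, "n": n,
                        "cohens_f2": r**2 / (1.0 - r**2) if abs(r) < 1 else np.inf,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["group", "metric", "clinical", "r", "p", "n", "cohens_f2"]
    )
    if len(out):
        reject, p_adj = fdr_bh(out["p"].to_numpy(), q)
        out["p_fdr"] = p_adj
        out["significant"] = reject
    else:
        out["p_fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
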