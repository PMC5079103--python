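"""Validation stage: the score as a moderator of parenting.

Tests whether the polygenic environmental-sensitivity score moderates the
effect of parenting (higher = more negative) on emotional symptoms via a
score x parenting interaction in OLS, reports the interaction's
incremental variance share from nested fits, checks for gene-environment
correlation, and produces 3 x 3 tertile cell-mean tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def residualize_phenotype(cohort: pd.DataFrame,
                          column: str = "emotional_symptoms") -> np.ndarray:
    """Standardized age- and sex-regressed residual of the outcome.

    OLS residuals of the symptom composite on {intercept, age, sex},
    re-standardized to mean 0, SD 1.  Degenerate (constant) covariates are
    dropped with a warning; with no usable covariate the result is the
    z-scored input.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 individuals")
    y = cohort[column].to_numpy(dtype=float)
    cols = [np.ones(len(cohort))]
    for name in ("age", "sex"):
        vec = cohort[name].to_numpy(dtype=float)
        if np.ptp(vec) == 0:
            warnings.warn(f"covariate '{name}' is constant; dropped")
            continue
        cols.append(vec)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sd = r.std()
    if sd == 0:
        raise ValueError("residual outcome has zero variance")
    return r / sd


@dataclass
class GxeFit:
    """Coefficients of the moderation model plus the interaction's dR^2."""

    coefficients: pd.DataFrame  # term, beta, ci_low, ci_high, p
    delta_r2_pct: float | None
    r2_with: float | None
    r2_without: float
    n: int

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]


def _ols_table(X: np.ndarray, y: np.ndarray,
               names: list[str]) -> tuple[pd.DataFrame, float]:
    n, k = X.shape
    if n <= k:
        raise ValueError("more terms than observations")
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"rank-deficient design (terms: {names})")
    XtX_inv = np.linalg.inv(XtX)
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tval = b / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    tcrit = stats.t.ppf(0.975, df)
    table = pd.DataFrame({
        "term": names,
        "beta": b,
        "se": se,
        "ci_low": b - tcrit * se,
        "ci_high": b + tcrit * se,
        "p": p,
    })
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return table, r2


def fit_gxe_model(
    outcome: np.ndarray,
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
    include_interaction: bool = True,
) -> GxeFit:
    """OLS moderation model with nested-fit incremental R^2.

    Terms: intercept, score, exposure, covariates and (optionally) the
    score x exposure product.  ``delta_r2_pct`` is 100 x (R^2 with - R^2
    without the interaction), both fits on the identical rows (listwise
    deletion applied first).
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        C = np.empty((len(y), 0))
        cov_names = []

    ok = np.isfinite(y) & np.isfinite(s) & np.isfinite(e)
    if C.shape[1]:
        ok &= np.all(np.isfinite(C), axis=1)
    y, s, e, C = y[ok], s[ok], e[ok], C[ok]
    n = len(y)

    inter = s * e
    if include_interaction and np.ptp(inter) == 0:
        raise ValueError("interaction column has zero variance")

    names0 = ["intercept", "score", "exposure"] + cov_names
    X0 = np.column_stack([np.ones(n), s, e, C])
    table0, r2_without = _ols_table(X0, y, names0)

    if not include_interaction:
        return GxeFit(coefficients=table0, delta_r2_pct=None,
                      r2_with=None, r2_without=r2_without, n=n)

    X1 = np.column_stack([X0, inter])
    table1, r2_with = _ols_table(X1, y, names0 + ["score_x_exposure"])
    return GxeFit(
        coefficients=table1,
        delta_r2_pct=100.0 * (r2_with - r2_without),
        r2_with=r2_with,
        r2_without=r2_without,
        n=n,
    )


def test_gene_environment_correlation(
    score: np.ndarray,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress each parenting measure on the score (+ covariates).

    A significant score coefficient indicates gene-environment
    correlation, which would confound the moderation test.  Returns one
    row per exposure measure with beta, CI and p for the score term.
    """
    s = np.asarray(score, dtype=float)
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        C = np.empty((len(s), 0))
        cov_names = []

    rows = []
    for col in exposures.columns:
        y = exposures[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(s)
        if C.shape[1]:
            ok &= np.all(np.isfinite(C), axis=1)
        X = np.column_stack([np.ones(int(ok.sum())), s[ok], C[ok]])
        table, _ = _ols_table(X, y[ok], ["intercept", "score"] + cov_names)
        c = table.set_index("term").loc["score"]
        rows.append({
            "exposure": col, "beta": c["beta"], "se": c["se"],
            "ci_low": c["ci_low"], "ci_high": c["ci_high"], "p": c["p"],
            "n": int(ok.sum()),
        })
    return pd.DataFrame(rows)


def _tertiles(x: np.ndarray) -> np.ndarray:
    """Equal-count tertile labels 0/1/2 by rank, stable in input order."""
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return np.minimum(ranks * 3 // n, 2)


def tertile_cell_means(
    outcome: np.ndarray,
    score: np.ndarray,
    exposure: np.ndarray,
) -> pd.DataFrame:
    """3 x 3 table of outcome means by score and exposure tertiles.

    Rows: score tertile (low/moderate/high sensitivity); columns within
    each row: exposure tertile (here low exposure = positive parenting).
    Returns a long table with cell mean, SE and n.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < 9:
        raise ValueError("need at least 9 observations for 3x3 tertiles")
    for v, name in ((score, "score"), (exposure, "exposure")):
        if len(np.unique(v)) < 3:
            raise ValueError(f"too few distinct {name} values for tertiles")
    st = _tertiles(np.asarray(score, dtype=float))
    et = _tertiles(np.asarray(exposure, dtype=float))
    labels = ["low", "moderate", "high"]
    rows = []
    for i in range(3):
        for j in range(3):
            mask = (st == i) & (et == j)
            n = int(mask.sum())
            cell = y[mask]
            rows.append({
                "score_tertile": labels[i],
                "exposure_tertile": labels[j],
                "mean": float(cell.mean()) if n else np.nan,
                "se": float(cell.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            })
    return pd.DataFrame(rows)


def gxe_threshold_sweep(
    outcome: np.ndarray,
    scores: pd.DataFrame,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the moderation model at every score threshold.

    Returns a tidy long table (threshold, term, beta, ci_low, ci_high, p,
    delta_r2_pct, n) with one block of rows per threshold column.
    """
    out = []
    for label in scores.columns:
        fit = fit_gxe_model(outcome, scores[label].to_numpy(), exposure,
                            covariates=covariates, include_interaction=True)
        block = fit.coefficients.copy()
        block.insert(0, "threshold", label)
        block["delta_r2_pct"] = fit.delta_r2_pct
        block["n"] = fit.n
        out.append(block)
    return pd.concat(out, ignore_index=True)
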