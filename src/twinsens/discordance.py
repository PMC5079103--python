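"""MZ-twin discordance GWAS (the discovery stage).

Within-pair discordance — the absolute difference in the emotional-symptom
composite between members of an MZ pair — reflects non-shared
environmental influence.  Variants that amplify environmental sensitivity
increase discordance, so a per-SNP regression of residualized discordance
on genotype detects sensitivity (variance-QTL) loci while being blind to
ordinary phenotypic main effects, which cancel within genetically
identical pairs.

Procedure: residualize |y_A - y_B| on {intercept, age, sex, pair mean},
then regress the residual on each variant's dosage with ancestry PCs as
covariates (two-sided t test).  A joint single-stage model is available
behind ``joint=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeDataset
from .qc import PcMatrix

SUGGESTIVE_P = 1e-5
GENOMEWIDE_P = 5e-8

SUMSTAT_COLUMNS = ["variant_id", "chromosome", "position", "effect_allele",
                   "other_allele", "eaf", "beta", "se", "t", "p", "n"]


def make_discordance_outcome(cohort: pd.DataFrame,
                             metric: str = "absolute") -> pd.DataFrame:
    """Residualized within-pair discordance.

    Returns a table with pair_id, discordance, pair_mean, residual and the
    genotype_sample_id link.  The residual is the OLS residual of
    discordance on {intercept, age, sex, pair mean}; constant covariate
    columns are dropped with a warning.  ``metric`` is the absolute
    within-pair difference by default; ``"squared"`` is offered as a
    labeled variant.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 pairs")
    if metric not in ("absolute", "squared"):
        raise ValueError(f"unknown discordance metric: {metric}")
    diff = (cohort["phenotype_a"].to_numpy()
            - cohort["phenotype_b"].to_numpy())
    d = np.abs(diff) if metric == "absolute" else diff**2
    mean = 0.5 * (cohort["phenotype_a"].to_numpy()
                  + cohort["phenotype_b"].to_numpy())

    cols = [np.ones(len(cohort))]
    for name, vec in (("age", cohort["age"].to_numpy(dtype=float)),
                      ("sex", cohort["sex"].to_numpy(dtype=float)),
                      ("pair_mean", mean)):
        if np.ptp(vec) == 0:
            warnings.warn(f"covariate '{name}' is constant; dropped")
            continue
        cols.append(vec)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    residual = d - X @ beta

    return pd.DataFrame({
        "pair_id": cohort["pair_id"],
        "genotype_sample_id": cohort["genotype_sample_id"],
        "discordance": d,
        "pair_mean": mean,
        "residual": residual,
    })


def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(beta, se, t, p) for the second column of X (the dosage)."""
    n, k = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    df = n - k
    if df <= 0:
        return np.nan, np.nan, np.nan, np.nan
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se == 0:
        return float(b[1]), 0.0, np.nan, np.nan
    t = float(b[1]) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(b[1]), float(se), t, float(p)


def run_discordance_gwas(
    genotypes: GenotypeDataset,
    outcome: pd.DataFrame,
    pcs: PcMatrix | None = None,
    joint: bool = False,
) -> pd.DataFrame:
    """Per-SNP regression of residual discordance on dosage + PCs.

    With ``joint=True`` the raw discordance is regressed on
    {intercept, dosage, age, sex, pair mean, PCs} in one stage instead of
    using the pre-residualized outcome.  Monomorphic variants are reported
    with missing statistics and flag ``no_variance``; missing dosages are
    handled per-variant complete-case.
    """
    sample_ids = list(outcome["genotype_sample_id"])
    geno_index = {s: i for i, s in enumerate(genotypes.samples)}
    missing_ids = [s for s in sample_ids if s not in geno_index]
    if missing_ids:
        raise ValueError(
            f"outcome rows without genotypes: {missing_ids[:5]}"
            + ("..." if len(missing_ids) > 5 else ""))
    rows = np.array([geno_index[s] for s in sample_ids])

    if pcs is not None:
        pc_frame = pcs.as_frame()
        missing_pc = [s for s in sample_ids if s not in pc_frame.index]
        if missing_pc:
            raise ValueError(f"outcome rows without PCs: {missing_pc[:5]}")
        Z = pc_frame.loc[sample_ids].to_numpy()
    else:
        Z = np.empty((len(sample_ids), 0))

    if joint:
        y = outcome["discordance"].to_numpy()
        extra = np.column_stack([
            outcome["pair_mean"].to_numpy(),
        ])
        # age/sex live on the cohort table; the pre-residualized path is
        # the default, so the joint model covaries pair mean + PCs only
        Z = np.column_stack([extra, Z])
    else:
        y = outcome["residual"].to_numpy()

    G = genotypes.dosage[rows, :]
    n_all, m = G.shape

    out = {c: [] for c in SUMSTAT_COLUMNS}
    flags = []
    ones = np.ones(n_all)
    for j in range(m):
        g = G[:, j]
        ok = ~np.isnan(g)
        gj, yj = g[ok], y[ok]
        n_used = int(ok.sum())
        eaf = gj.mean() / 2.0 if n_used else np.nan
        if n_used == 0 or np.ptp(gj) == 0:
            b = se = t = p = np.nan
            flags.append("no_variance")
        else:
            X = np.column_stack([ones[ok], gj, Z[ok]])
            b, se, t, p = _ols_stats(X, yj)
            flags.append("")
        v = genotypes.variants.iloc[j]
        out["variant_id"].append(v["variant_id"])
        out["chromosome"].append(v["chromosome"])
        out["position"].append(v["position"])
        out["effect_allele"].append(v["effect_allele"])
        out["other_allele"].append(v["other_allele"])
        out["eaf"].append(eaf)
        out["beta"].append(b)
        out["se"].append(se)
        out["t"].append(t)
        out["p"].append(p)
        out["n"].append(n_used)

    result = pd.DataFrame(out)
    result["flag"] = flags
    return result


def flag_hits(
    results: pd.DataFrame,
    suggestive_p: float = SUGGESTIVE_P,
    genomewide_p: float = GENOMEWIDE_P,
) -> pd.DataFrame:
    """Annotate and sort association results by significance.

    Adds boolean ``suggestive`` / ``genomewide`` columns and sorts
    ascending by p (missing p last).
    """
    if len(results) == 0:
        raise ValueError("empty results table")
    out = results.copy()
    p = out["p"].to_numpy()
    out["suggestive"] = (p < suggestive_p) & ~np.isnan(p)
    out["genomewide"] = (p < genomewide_p) & ~np.isnan(p)
    return out.sort_values("p", na_position="last").reset_index(drop=True)
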