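"""Treatment stage: score x treatment-arm moderation of CBT response.

Response is the change in the Clinician's Severity Rating (CSR, 0-8) of
the primary anxiety diagnosis from baseline to each post-baseline time
point (negative = improvement), modelled with a full-maximum-likelihood
linear mixed model: fixed linear + quadratic time, mean-centred baseline
severity, age, sex, primary diagnosis, treatment arm and ancestry PCs;
random intercepts for subject and (above it) trial.  Under this coding a
positive predictor coefficient means a poorer response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .config import ARM_NAMES
from .prs import ScoreMatrix

TIME_POINTS = [("csr_post", 0, 0.0), ("csr_3m", 1, 3.0),
               ("csr_6m", 2, 6.0), ("csr_12m", 3, 12.0)]

REMISSION_CSR = 4  # CSR >= 4 defines diagnostic caseness


def score_column_name(threshold_label: str) -> str:
    """Formula-safe column name for a threshold label ('0.05' -> score_0p05)."""
    return "score_" + str(threshold_label).replace(".", "p")


def threshold_label(score_column: str) -> str:
    return score_column.removeprefix("score_").replace("p", ".")


def attach_scores(records: pd.DataFrame, scores: ScoreMatrix) -> pd.DataFrame:
    """Merge standardized score columns (named ``score_<threshold>``,
    with '.' spelt 'p' so the names are usable in model formulas)."""
    sc = scores.scores.copy()
    sc.columns = [score_column_name(c) for c in sc.columns]
    sc.index.name = "subject_id"
    return records.merge(sc.reset_index(), on="subject_id", how="left")


def build_response_table(records: pd.DataFrame,
                         outcome: str = "change") -> pd.DataFrame:
    """Long response table: one row per observed post-baseline CSR.

    ``response = CSR_t - CSR_baseline`` by default; ``outcome="followup"``
    uses the follow-up CSR itself (with baseline still a mean-centred
    covariate in the model).  Time is coded both as an index (0..3) and
    in months since treatment end.  Subjects with no post-baseline
    assessment are excluded with a warning.
    """
    if outcome not in ("change", "followup"):
        raise ValueError(f"unknown outcome coding: {outcome}")
    csr_cols = ["csr_baseline"] + [c for c, _, _ in TIME_POINTS]
    vals = records[csr_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 8:
            raise ValueError("CSR values outside 0..8")

    keep_cols = [c for c in records.columns if c not in
                 {c for c, _, _ in TIME_POINTS}]
    rows = []
    n_dropped = 0
    for _, rec in records.iterrows():
        any_obs = False
        for col, t_idx, months in TIME_POINTS:
            csr_t = rec[col]
            if pd.isna(csr_t):
                continue
            any_obs = True
            row = {k: rec[k] for k in keep_cols}
            row["time_idx"] = t_idx
            row["months"] = months
            row["csr_t"] = csr_t
            row["response"] = (csr_t - rec["csr_baseline"]
                               if outcome == "change" else csr_t)
            rows.append(row)
        if not any_obs:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"{n_dropped} subjects with no post-baseline CSR "
                      "excluded")
    table = pd.DataFrame(rows)
    table["csr0_c"] = table["csr_baseline"] - table["csr_baseline"].mean()
    table["age_c"] = table["age"] - table["age"].mean()
    return table


@dataclass
class MixedModelFit:
    """Full-ML mixed-model fit summary."""

    fixed_effects: pd.DataFrame  # term, beta, se, ci_low, ci_high, p
    variance_components: dict    # subject, trial, residual
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_trials: int
    formula: str = ""
    fixed_prediction_var: float = np.nan
    fitted_fixed: np.ndarray | None = field(default=None, repr=False)
    used_data: pd.DataFrame | None = field(default=None, repr=False)
    _result: object = field(default=None, repr=False)

    def coef(self, term: str) -> pd.Series:
        return self.fixed_effects.set_index("term").loc[term]

    def contrast(self, terms: dict[str, float]) -> dict:
        """Linear combination of fixed effects with Wald CI and p."""
        res = self._result
        names = list(res.fe_params.index)
        L = np.zeros(len(names))
        for term, wgt in terms.items():
            L[names.index(term)] = wgt
        est = float(L @ res.fe_params.to_numpy())
        cov = res.cov_params().iloc[: len(names), : len(names)].to_numpy()
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return {"beta": est, "se": se, "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se, "p": p}


BASE_TERMS = ("time_idx", "I(time_idx**2)", "csr0_c", "age_c", "C(sex)",
              "C(primary_diagnosis)")


def _formula(score_column: str | None, arm_term: bool,
             interaction: bool, extra_terms: tuple[str, ...],
             pc_columns: tuple[str, ...]) -> str:
    terms = list(BASE_TERMS) + list(pc_columns) + list(extra_terms)
    if arm_term:
        terms.append("C(arm)")
    if score_column:
        terms.append(score_column)
        if interaction:
            terms.append(f"C(arm):{score_column}")
    return "response ~ " + " + ".join(terms)


def fit_response_lmm(
    table: pd.DataFrame,
    score_column: str | None = None,
    arm_term: bool = True,
    interaction: bool = False,
    extra_terms: tuple[str, ...] = (),
    pc_columns: tuple[str, ...] = (),
    formula: str | None = None,
) -> MixedModelFit:
    """Fit the longitudinal response model by full maximum likelihood.

    Random intercepts: trial (grouping factor) and subject (variance
    component nested in trial).  Non-convergence is flagged on the
    returned fit, never silently replaced.
    """
    if formula is None:
        formula = _formula(score_column, arm_term, interaction,
                           extra_terms, pc_columns)
    data = table.copy()
    data["arm"] = pd.Categorical(data["arm"],
                                 categories=[a for a in ARM_NAMES
                                             if a in set(data["arm"])])
    # listwise deletion over every column the formula mentions
    used_cols = [c for c in data.columns
                 if c == "response" or (c in formula and c not in
                                        ("response",))]
    data = data.dropna(subset=[c for c in used_cols
                               if data[c].dtype.kind in "fiub"])

    single_trial = data["trial_id"].nunique() < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_trial:
            # one stratum: trial intercept unidentifiable; subject only
            model = sm.MixedLM.from_formula(
                formula, data=data, groups="subject_id", re_formula="1")
        else:
            model = sm.MixedLM.from_formula(
                formula, data=data, groups="trial_id", re_formula="1",
                vc_formula={"subject": "0 + C(subject_id)"})
        # full ML; lbfgs occasionally reports convergence at a spurious
        # optimum with an absurd trial variance, so rerun a ladder of
        # optimizers whenever the fit looks off and keep the best llf
        resp_var = float(np.var(model.endog))
        result = model.fit(reml=False, method="lbfgs", maxiter=500)

        def _suspicious(res) -> bool:
            if not res.converged:
                return True
            trial_var = (float(res.cov_re.iloc[0, 0]) * float(res.scale)
                         if res.cov_re.size else 0.0)
            return trial_var > max(resp_var, 1e-8)

        if _suspicious(result):
            for method in ("powell", "bfgs"):
                try:
                    alt = model.fit(reml=False, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if alt.llf > result.llf:
                    result = alt
                if result.converged and not _suspicious(result):
                    break

    fe = result.fe_params
    se = result.bse_fe
    z = fe / se
    p = 2 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame({
        "term": fe.index,
        "beta": fe.to_numpy(),
        "se": se.to_numpy(),
        "ci_low": fe.to_numpy() - 1.96 * se.to_numpy(),
        "ci_high": fe.to_numpy() + 1.96 * se.to_numpy(),
        "p": p,
    })

    scale = float(result.scale)
    if single_trial:
        vc = {"trial": 0.0,
              "subject": float(result.cov_re.iloc[0, 0]) * scale
              if result.cov_re.size else 0.0,
              "residual": scale}
    else:
        trial_var = float(result.cov_re.iloc[0, 0]) * scale \
            if result.cov_re.size else 0.0
        subj_var = float(result.vcomp[0]) * scale if len(result.vcomp) \
            else 0.0
        vc = {"trial": trial_var, "subject": subj_var, "residual": scale}

    fixed_pred = np.asarray(model.exog) @ fe.to_numpy()
    return MixedModelFit(
        fixed_effects=fixed,
        variance_components=vc,
        loglik=float(result.llf),
        converged=bool(result.converged),
        n_obs=int(len(data)),
        n_subjects=int(data["subject_id"].nunique()),
        n_trials=int(data["trial_id"].nunique()),
        formula=formula,
        fixed_prediction_var=float(np.var(fixed_pred)),
        fitted_fixed=fixed_pred,
        used_data=data,
        _result=result,
    )


def simulate_from_fit(fit: MixedModelFit,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Parametric draw from a fitted model (for bootstrap checks).

    Returns a copy of the rows the fit used with ``response`` replaced by
    ``X b + u_trial + u_subject + eps`` drawn at the estimated variance
    components.
    """
    data = fit.used_data.copy()
    subj = data["subject_id"].to_numpy()
    trial = data["trial_id"].to_numpy()
    u_subj = {s: rng.normal(0, np.sqrt(fit.variance_components["subject"]))
              for s in pd.unique(subj)}
    u_trial = {t: rng.normal(0, np.sqrt(fit.variance_components["trial"]))
               for t in pd.unique(trial)}
    eps = rng.normal(0, np.sqrt(fit.variance_components["residual"]),
                     size=len(data))
    data["response"] = (fit.fitted_fixed
                        + np.array([u_subj[s] for s in subj])
                        + np.array([u_trial[t] for t in trial])
                        + eps)
    return data


def variance_explained(fit_with: MixedModelFit,
                       fit_without: MixedModelFit) -> float:
    """Percent increment in the marginal fixed-effect variance share.

    Share = Var(X b) / (Var(X b) + subject + trial + residual variance);
    the returned value is 100 x (share_with - share_without).  Requires
    nested fixed-effect specifications fitted on the same rows.
    """
    terms_w = set(fit_with.fixed_effects["term"])
    terms_wo = set(fit_without.fixed_effects["term"])
    if not terms_wo <= terms_w:
        raise ValueError("fixed-effect specifications are not nested")
    if fit_with.n_obs != fit_without.n_obs:
        raise ValueError("fits use different row sets")

    def share(fit: MixedModelFit) -> float:
        v = fit.fixed_prediction_var
        tot = (v + fit.variance_components["subject"]
               + fit.variance_components["trial"]
               + fit.variance_components["residual"])
        return v / tot if tot > 0 else 0.0

    return 100.0 * (share(fit_with) - share(fit_without))


@dataclass
class ContrastResult:
    """Overall, per-arm and pairwise-interaction score effects."""

    overall: pd.DataFrame       # threshold, beta, se, ci, p, r2_pct
    per_arm: pd.DataFrame       # threshold, arm, beta, se, ci, p, r2_pct, n
    interactions: pd.DataFrame  # threshold, contrast, beta, se, ci, p


def score_treatment_effects(
    table: pd.DataFrame,
    score_columns: list[str],
    pc_columns: tuple[str, ...] = (),
    extra_terms: tuple[str, ...] = (),
    min_arm_n: int = 10,
) -> ContrastResult:
    """Overall, per-arm and pairwise arm x score effects per threshold.

    Per-arm effects come from arm-subset fits (no arm term) with the
    marginal variance-explained increment of the score; pairwise
    interaction contrasts come from the pooled model with
    ``C(arm):score`` terms.  Arms with fewer than ``min_arm_n`` subjects
    are skipped with a warning.
    """
    arms = [a for a in ARM_NAMES if a in set(table["arm"])]
    overall_rows, arm_rows, inter_rows = [], [], []

    for col in score_columns:
        label = threshold_label(col)
        sub = table.dropna(subset=[col])

        base = fit_response_lmm(sub, score_column=None, arm_term=True,
                                pc_columns=pc_columns,
                                extra_terms=extra_terms)
        with_score = fit_response_lmm(sub, score_column=col, arm_term=True,
                                      pc_columns=pc_columns,
                                      extra_terms=extra_terms)
        c = with_score.coef(col)
        overall_rows.append({
            "threshold": label, "beta": c["beta"], "se": c["se"],
            "ci_low": c["ci_low"], "ci_high": c["ci_high"], "p": c["p"],
            "r2_pct": variance_explained(with_score, base),
            "n": with_score.n_subjects,
        })

        for arm in arms:
            arm_tab = sub[sub["arm"] == arm]
            if arm_tab["subject_id"].nunique() < min_arm_n:
                warnings.warn(f"arm '{arm}' below {min_arm_n} subjects; "
                              "per-arm fit skipped")
                continue
            fit0 = fit_response_lmm(arm_tab, score_column=None,
                                    arm_term=False, pc_columns=pc_columns,
                                    extra_terms=extra_terms)
            fit1 = fit_response_lmm(arm_tab, score_column=col,
                                    arm_term=False, pc_columns=pc_columns,
                                    extra_terms=extra_terms)
            c = fit1.coef(col)
            arm_rows.append({
                "threshold": label, "arm": arm, "beta": c["beta"],
                "se": c["se"], "ci_low": c["ci_low"],
                "ci_high": c["ci_high"], "p": c["p"],
                "r2_pct": variance_explained(fit1, fit0),
                "n": fit1.n_subjects,
            })

        if len(arms) == 3:
            inter_fit = fit_response_lmm(sub, score_column=col,
                                         arm_term=True, interaction=True,
                                         pc_columns=pc_columns,
                                         extra_terms=extra_terms)
            t_grp = f"C(arm)[T.group]:{col}"
            t_pl = f"C(arm)[T.parent_led]:{col}"
            pairs = {
                "individual_vs_group": {t_grp: 1.0},
                "individual_vs_parent_led": {t_pl: 1.0},
                "group_vs_parent_led": {t_pl: 1.0, t_grp: -1.0},
            }
            for name, combo in pairs.items():
                ct = inter_fit.contrast(combo)
                inter_rows.append({"threshold": label, "contrast": name,
                                   **ct})

    return ContrastResult(
        overall=pd.DataFrame(overall_rows),
        per_arm=pd.DataFrame(arm_rows),
        interactions=pd.DataFrame(inter_rows),
    )


def comorbidity_sensitivity(
    table: pd.DataFrame,
    score_columns: list[str],
    pc_columns: tuple[str, ...] = (),
) -> ContrastResult:
    """Re-run the score effects adjusting for comorbid internalizing
    disorder on the complete-case subset."""
    if table["comorbid_internalizing"].isna().all():
        raise ValueError("comorbid_internalizing entirely missing")
    sub = table.dropna(subset=["comorbid_internalizing"]).copy()
    return score_treatment_effects(
        sub, score_columns, pc_columns=pc_columns,
        extra_terms=("comorbid_internalizing",))


def remission_table(
    records: pd.DataFrame,
    score: np.ndarray,
    by_arm: bool = True,
) -> pd.DataFrame:
    """Post-treatment remission rates by score tertile (x arm).

    Remission = post-treatment CSR below the caseness cut-off
    (:data:`REMISSION_CSR`).  Subjects without a post-treatment CSR are
    excluded; empty cells report rate NaN with n = 0.
    """
    from .gxe import _tertiles

    score = np.asarray(score, dtype=float)
    ok = records["csr_post"].notna().to_numpy() & np.isfinite(score)
    rec = records[ok]
    remit = (rec["csr_post"].to_numpy() < REMISSION_CSR).astype(float)
    tert = _tertiles(score[ok])
    labels = ["low", "moderate", "high"]

    groups = [("all",)] if not by_arm else [(a,) for a in ARM_NAMES]
    rows = []
    for (arm,) in groups:
        arm_mask = np.ones(len(rec), dtype=bool) if arm == "all" \
            else (rec["arm"] == arm).to_numpy()
        for i, lab in enumerate(labels):
            mask = arm_mask & (tert == i)
            n = int(mask.sum())
            if n == 0:
                rows.append({"arm": arm, "score_tertile": lab,
                             "remission_rate": np.nan, "se": np.nan, "n": 0})
                continue
            r = float(remit[mask].mean())
            rows.append({
                "arm": arm, "score_tertile": lab, "remission_rate": r,
                "se": float(np.sqrt(r * (1 - r) / n)), "n": n,
            })
    return pd.DataFrame(rows)


@dataclass
class MatchResult:
    """1:1 propensity matches for one arm pair with balance diagnostics."""

    arm_a: str
    arm_b: str
    matched_a: list[str]
    matched_b: list[str]
    balance: pd.DataFrame  # covariate, smd_before, smd_after
    caliper: float
    n_candidates: tuple[int, int]

    @property
    def matched_ids(self) -> list[str]:
        return list(self.matched_a) + list(self.matched_b)


def _smd(x_a: np.ndarray, x_b: np.ndarray) -> float:
    va, vb = x_a.var(ddof=1), x_b.var(ddof=1)
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_a.mean() - x_b.mean()) / pooled)


def propensity_match(
    records: pd.DataFrame,
    covariate_list: list[str],
    caliper_sd: float = 0.2,
    metric: str = "mahalanobis",
) -> dict[tuple[str, str], MatchResult]:
    """Pairwise 1:1 propensity matching across arms, without replacement.

    For each arm pair, a logistic model of arm membership on the stated
    covariates (complete cases; categorical covariates dummy-coded) gives
    logit propensities.  Candidates must sit within a caliper of
    ``caliper_sd`` SDs of the logit; among them, ``metric`` picks the
    partner:

    * ``"mahalanobis"`` (default): nearest Mahalanobis distance on the
      standardized covariates — balances every matching covariate, not
      just the propensity, which matters at modest sample sizes;
    * ``"logit"``: plain nearest neighbour on the logit itself.

    Returns before/after standardized mean differences per covariate.
    """
    if metric not in ("mahalanobis", "logit"):
        raise ValueError(f"unknown matching metric: {metric}")
    results: dict[tuple[str, str], MatchResult] = {}
    arms = [a for a in ARM_NAMES if a in set(records["arm"])]
    for i in range(len(arms)):
        for j in range(i + 1, len(arms)):
            arm_a, arm_b = arms[i], arms[j]
            sub = records[records["arm"].isin([arm_a, arm_b])]
            sub = sub.dropna(subset=covariate_list)
            X = pd.get_dummies(sub[covariate_list], drop_first=True)
            X = X.astype(float)
            Xz = (X - X.mean()) / X.std(ddof=0).replace(0, 1.0)
            y = (sub["arm"] == arm_b).astype(float).to_numpy()

            design = sm.add_constant(Xz.to_numpy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                logit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            lp = design @ logit.params  # logit-scale propensity

            idx_a = np.flatnonzero(y == 0)
            idx_b = np.flatnonzero(y == 1)
            caliper = caliper_sd * float(np.std(lp, ddof=1))

            Xn_all = Xz.to_numpy()
            cov = np.cov(Xn_all, rowvar=False)
            cov += 1e-8 * np.eye(cov.shape[0])
            cov_inv = np.linalg.inv(cov)

            # match the smaller group into the larger one
            if len(idx_b) <= len(idx_a):
                treated, pool = idx_b, idx_a
            else:
                treated, pool = idx_a, idx_b
            order = treated[np.argsort(lp[treated])[::-1]]
            available = set(pool.tolist())
            pairs = []
            for t in order:
                if not available:
                    break
                cand = np.fromiter(available, dtype=int)
                ok = np.abs(lp[cand] - lp[t]) <= caliper
                cand = cand[ok]
                if len(cand) == 0:
                    continue
                if metric == "mahalanobis":
                    diff = Xn_all[cand] - Xn_all[t]
                    dist = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
                else:
                    dist = np.abs(lp[cand] - lp[t])
                k = int(np.argmin(dist))
                pairs.append((t, cand[k]))
                available.discard(int(cand[k]))

            ids = sub["subject_id"].to_numpy()
            m_t = [t for t, _ in pairs]
            m_c = [c for _, c in pairs]
            if len(idx_b) <= len(idx_a):
                matched_b, matched_a = m_t, m_c
            else:
                matched_a, matched_b = m_t, m_c

            bal_rows = []
            Xn = Xz.to_numpy()
            for col_k, name in enumerate(X.columns):
                before = _smd(Xn[idx_a, col_k], Xn[idx_b, col_k])
                if pairs:
                    after = _smd(Xn[matched_a, col_k], Xn[matched_b, col_k])
                else:
                    after = np.nan
                bal_rows.append({"covariate": name,
                                 "smd_before": before, "smd_after": after})

            results[(arm_a, arm_b)] = MatchResult(
                arm_a=arm_a, arm_b=arm_b,
                matched_a=list(ids[matched_a]),
                matched_b=list(ids[matched_b]),
                balance=pd.DataFrame(bal_rows),
                caliper=caliper,
                n_candidates=(len(idx_a), len(idx_b)),
            )
    return results


def matched_subject_ids(
    matches: dict[tuple[str, str], MatchResult]
) -> list[str]:
    """Union of subjects appearing in any pairwise matched set."""
    ids: set[str] = set()
    for m in matches.values():
        ids.update(m.matched_ids)
    return sorted(ids)
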