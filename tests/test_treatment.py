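"""Longitudinal response model, contrasts, remission and matching."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from twinsens import SimulationConfig, draw_truth, simulate_genotypes
from twinsens.simulate import simulate_treatment_cohort
from twinsens.treatment import (
    build_response_table,
    comorbidity_sensitivity,
    fit_response_lmm,
    propensity_match,
    remission_table,
    score_treatment_effects,
    variance_explained,
)


def _records(**kw):
    base = dict(n_pairs=0, n_unrelated=0, n_subjects=300, n_trials=3,
                n_variants=30, n_sensitivity_loci=5, n_main_loci=0,
                seed=17)
    base.update(kw)
    cfg = SimulationConfig(**base).validate()
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    rec = simulate_treatment_cohort(ds, truth, cfg)
    rows = np.arange(cfg.n_subjects)
    s = truth.true_sensitivity(ds.subset_samples(rows))
    return rec, s, cfg


# -------------------------------------------------------- response table

def test_response_sign_convention():
    rec = pd.DataFrame({
        "subject_id": ["a"], "trial_id": ["t0"], "arm": ["group"],
        "primary_diagnosis": ["GAD"], "age": [10.0], "sex": [1],
        "csr_baseline": [6], "csr_post": [3.0], "csr_3m": [np.nan],
        "csr_6m": [2.0], "csr_12m": [np.nan],
    })
    table = build_response_table(rec)
    assert len(table) == 2  # missing assessments contribute no rows
    post = table[table["time_idx"] == 0].iloc[0]
    assert post["response"] == -3.0


def test_row_count_matches_manual_tally(rng):
    rec, _, _ = _records(n_subjects=5, missing_rate=0.4)
    expected = int(rec[["csr_post", "csr_3m", "csr_6m", "csr_12m"]]
                   .notna().sum().sum())
    assert len(build_response_table(rec)) == expected


def test_followup_outcome_coding_shifts_only_the_baseline_term():
    """With baseline severity as a covariate, modelling the follow-up
    CSR instead of the change score leaves every other fixed effect
    unchanged (the two outcomes differ by the baseline column)."""
    rec, s, _ = _records(n_subjects=150, seed=23)
    rec["score_x"] = (s - s.mean()) / s.std()
    change = build_response_table(rec, outcome="change")
    follow = build_response_table(rec, outcome="followup")
    assert np.allclose(follow["response"],
                       change["response"] + change["csr_baseline"])
    fit_c = fit_response_lmm(change, score_column="score_x")
    fit_f = fit_response_lmm(follow, score_column="score_x")
    bc = fit_c.fixed_effects.set_index("term")["beta"]
    bf = fit_f.fixed_effects.set_index("term")["beta"]
    assert bf["score_x"] == pytest.approx(bc["score_x"], abs=1e-4)
    assert bf["csr0_c"] == pytest.approx(bc["csr0_c"] + 1.0, abs=1e-4)


def test_out_of_range_csr_rejected():
    rec = pd.DataFrame({
        "subject_id": ["a"], "trial_id": ["t"], "arm": ["group"],
        "primary_diagnosis": ["GAD"], "age": [10.0], "sex": [1],
        "csr_baseline": [6], "csr_post": [9.0], "csr_3m": [np.nan],
        "csr_6m": [np.nan], "csr_12m": [np.nan],
    })
    with pytest.raises(ValueError, match="0..8"):
        build_response_table(rec)


# ---------------------------------------------------------- mixed model

def test_degenerate_random_effects_reduce_to_ols():
    """When the ML variance-component estimates sit on the zero boundary,
    the mixed-model fixed effects coincide with plain OLS.

    The ML estimate of a truly-zero variance component lands exactly at
    the boundary for about half of all datasets; this fixture is one
    where it does, so the reduction can be asserted tightly.
    """
    rec, s, _ = _records(subject_sd=0.0, trial_sd=0.0, n_subjects=200,
                         missing_rate=0.0, arm_moderation=(0.0, 0.0, 0.0),
                         seed=37)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    fit = fit_response_lmm(table, score_column="score_x")
    assert fit.variance_components["trial"] < 1e-8
    assert fit.variance_components["subject"] < 1e-3

    ols = smf.ols(fit.formula, data=fit.used_data).fit()
    mine = fit.fixed_effects.set_index("term")["beta"]
    for term in ols.params.index:
        assert mine[term] == pytest.approx(ols.params[term], abs=1e-6)


def test_positive_coefficient_means_poorer_response():
    """A covariate that worsens response (less CSR reduction) gets a
    positive fixed-effect estimate under the change-score coding."""
    rec, s, _ = _records(n_subjects=400,
                         arm_moderation=(0.6, 0.6, 0.6), seed=29)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    fit = fit_response_lmm(table, score_column="score_x")
    c = fit.coef("score_x")
    assert c["beta"] > 0
    assert c["p"] < 0.01


def test_loglik_never_decreases_when_adding_a_fixed_effect():
    rec, s, _ = _records(n_subjects=150)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    base = fit_response_lmm(table)
    bigger = fit_response_lmm(table, score_column="score_x")
    assert bigger.loglik >= base.loglik - 1e-6


def test_variance_explained_reduces_to_ols_dr2_at_zero_variances():
    """With both fits' random variances estimated at the zero boundary,
    the marginal-share increment equals the OLS dR^2 computed with the
    same share definition (ML residual variance)."""
    rec, s, _ = _records(subject_sd=0.0, trial_sd=0.0, n_subjects=200,
                         missing_rate=0.0, arm_moderation=(0.0, 0.0, 0.0),
                         seed=37)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    with_score = fit_response_lmm(table, score_column="score_x")
    without = fit_response_lmm(table)
    for fit in (with_score, without):
        assert fit.variance_components["trial"] < 1e-2
        assert fit.variance_components["subject"] < 1e-2
    inc = variance_explained(with_score, without)

    ols1 = smf.ols(with_score.formula, data=with_score.used_data).fit()
    ols0 = smf.ols(without.formula, data=without.used_data).fit()

    def ols_share(res):
        v = np.var(res.fittedvalues)
        return v / (v + res.ssr / res.nobs)

    expected = 100 * (ols_share(ols1) - ols_share(ols0))
    assert inc == pytest.approx(expected, abs=0.05)
    # a null score's increment is itself essentially zero
    assert abs(inc) < 0.5


def test_variance_explained_tracks_real_score_effect():
    rec, s, _ = _records(n_subjects=250, subject_sd=0.0, trial_sd=0.0,
                         missing_rate=0.0, seed=31,
                         arm_moderation=(0.8, 0.8, 0.8))
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    with_score = fit_response_lmm(table, score_column="score_x")
    without = fit_response_lmm(table)
    inc = variance_explained(with_score, without)

    ols1 = smf.ols(with_score.formula, data=with_score.used_data).fit()
    ols0 = smf.ols(without.formula, data=without.used_data).fit()

    def ols_share(res):
        v = np.var(res.fittedvalues)
        return v / (v + res.ssr / res.nobs)

    # subject-level signal makes the reduced fit's subject variance
    # nonzero, so the LMM increment only approximates the OLS one
    expected = 100 * (ols_share(ols1) - ols_share(ols0))
    assert inc == pytest.approx(expected, abs=0.5)
    assert inc > 5.0


def test_non_nested_specs_rejected():
    rec, s, _ = _records(n_subjects=120)
    rec["score_x"] = s
    table = build_response_table(rec)
    a = fit_response_lmm(table, score_column="score_x", arm_term=False)
    b = fit_response_lmm(table, arm_term=True)
    with pytest.raises(ValueError, match="nested"):
        variance_explained(a, b)


def test_three_arms_give_three_contrasts():
    rec, s, _ = _records(n_subjects=200)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eff = score_treatment_effects(table, ["score_x"])
    assert len(eff.interactions) == 3
    assert set(eff.interactions["contrast"]) == {
        "individual_vs_group", "individual_vs_parent_led",
        "group_vs_parent_led"}
    assert len(eff.per_arm) == 3
    assert len(eff.overall) == 1


def test_tiny_arm_skipped_with_warning():
    rec, s, _ = _records(n_subjects=120)
    rec["score_x"] = (s - s.mean()) / s.std()
    # shrink one arm below the cut-off
    pl = rec[rec["arm"] == "parent_led"].index
    rec.loc[pl[5:], "arm"] = "group"
    table = build_response_table(rec)
    with pytest.warns(UserWarning, match="per-arm fit skipped"):
        eff = score_treatment_effects(table, ["score_x"], min_arm_n=10)
    assert set(eff.per_arm["arm"]) == {"individual", "group"}


# ------------------------------------------------------------- remission

def test_remission_threshold_is_csr_below_four():
    rec = pd.DataFrame({
        "subject_id": ["a", "b", "c"], "arm": ["group"] * 3,
        "csr_post": [3.0, 4.0, np.nan],
    })
    out = remission_table(rec, np.array([0.0, 1.0, 2.0]), by_arm=False)
    # subject c has no post CSR; of the remaining, a remits, b does not
    total_n = out["n"].sum()
    assert total_n == 2
    rates = out.dropna(subset=["remission_rate"])
    assert set(rates["remission_rate"]) <= {0.0, 1.0}


def test_all_severe_post_means_zero_remission(rng):
    n = 60
    rec = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "arm": ["individual", "group", "parent_led"] * (n // 3),
        "csr_post": np.full(n, 8.0),
    })
    out = remission_table(rec, rng.standard_normal(n))
    assert (out.dropna(subset=["remission_rate"])["remission_rate"]
            == 0).all()


def test_remission_rates_match_groupby_oracle(rng):
    rec, s, _ = _records(n_subjects=60)
    out = remission_table(rec, s)
    from twinsens.gxe import _tertiles
    ok = rec["csr_post"].notna().to_numpy()
    tert = _tertiles(s[ok])
    remit = (rec["csr_post"][ok] < 4).to_numpy()
    arms = rec["arm"][ok].to_numpy()
    labels = ["low", "moderate", "high"]
    for _, row in out.iterrows():
        mask = (arms == row["arm"]) & (tert == labels.index(
            row["score_tertile"]))
        assert row["n"] == mask.sum()
        if mask.sum():
            assert row["remission_rate"] == pytest.approx(
                remit[mask].mean())


# -------------------------------------------------------------- matching

MATCH_COVS = ["csr_baseline", "age", "primary_diagnosis",
              "comorbid_internalizing", "comorbid_externalizing",
              "parental_psychopathology"]


def test_unconfounded_allocation_matches_nearly_everyone():
    rec, _, _ = _records(n_subjects=400, confounded_allocation=False,
                         comorbid_missing_rate=0.0,
                         parental_missing_rate=0.0)
    matches = propensity_match(rec, MATCH_COVS)
    assert len(matches) == 3
    for (a, b), m in matches.items():
        n_small = min(m.n_candidates)
        assert len(m.matched_a) == len(m.matched_b)
        assert len(m.matched_a) > 0.85 * n_small


def test_confounded_allocation_balances_after_matching():
    rec, _, _ = _records(n_subjects=600, confounded_allocation=True,
                         comorbid_missing_rate=0.0,
                         parental_missing_rate=0.0, seed=41)
    matches = propensity_match(rec, MATCH_COVS)
    for m in matches.values():
        bal = m.balance.set_index("covariate")
        drivers = bal.loc[["csr_baseline", "age"]]
        # severity/age drive allocation; matching removes that imbalance
        assert drivers["smd_before"].abs().max() > 0.25
        assert (drivers["smd_after"].abs().max()
                < 0.6 * drivers["smd_before"].abs().max())
        assert drivers["smd_after"].abs().max() < 0.16
        # the remaining covariates sit at sampling noise either way
        assert (bal["smd_after"].abs().max()
                < max(0.25, bal["smd_before"].abs().max()))


# --------------------------------------------------------- comorbidity

def test_comorbidity_adjustment_keeps_schema():
    rec, s, _ = _records(n_subjects=200, comorbid_missing_rate=0.1)
    rec["score_x"] = (s - s.mean()) / s.std()
    table = build_response_table(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plain = score_treatment_effects(table, ["score_x"])
        adj = comorbidity_sensitivity(table, ["score_x"])
    assert list(adj.interactions.columns) == list(
        plain.interactions.columns)
    assert list(adj.per_arm.columns) == list(plain.per_arm.columns)


def test_comorbidity_entirely_missing_raises():
    rec, s, _ = _records(n_subjects=60)
    rec["comorbid_internalizing"] = np.nan
    rec["score_x"] = s
    table = build_response_table(rec)
    with pytest.raises(ValueError, match="missing"):
        comorbidity_sensitivity(table, ["score_x"])
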