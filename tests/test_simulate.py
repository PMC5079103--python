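"""Generator-level checks: the statistical structure the analysis assumes
must actually be present in the synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinsens import (
    SimulationConfig,
    draw_truth,
    simulate_genotypes,
    simulate_mz_cohort,
    simulate_treatment_cohort,
    simulate_validation_cohort,
    write_fixture_set,
)
from twinsens.config import ConfigError
from twinsens.simulate import cohort_slices


def _cfg(**kw) -> SimulationConfig:
    base = dict(n_pairs=0, n_unrelated=0, n_subjects=0, n_trials=1,
                n_variants=10, n_sensitivity_loci=0, n_main_loci=0, seed=5)
    base.update(kw)
    return SimulationConfig(**base).validate()


# ---------------------------------------------------------------- genotypes

def test_zero_variants_gives_empty_matrix():
    cfg = _cfg(n_pairs=7, n_variants=0)
    ds = simulate_genotypes(cfg)
    assert ds.dosage.shape == (7, 0)
    assert ds.n_variants == 0


def test_config_validation_names_offending_field():
    with pytest.raises(ConfigError, match="maf_range"):
        _cfg(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigError, match="ld_rho"):
        _cfg(ld_rho=1.0)
    with pytest.raises(ConfigError, match="noise_sd"):
        _cfg(noise_sd=-1.0)
    with pytest.raises(ConfigError, match="n_sensitivity_loci"):
        _cfg(n_variants=5, n_sensitivity_loci=4, n_main_loci=3)


def test_empirical_maf_matches_drawn_maf_at_half():
    cfg = _cfg(n_pairs=2500, n_variants=4, maf_range=(0.5, 0.5), ld_rho=0.0)
    ds = simulate_genotypes(cfg)
    # 2 * 2500 haplotype draws per variant
    se = np.sqrt(0.5 * 0.5 / 5000)
    assert np.all(np.abs(ds.effect_allele_frequency() - 0.5) < 3 * se)


def test_ld_block_r2_matches_latent_model_oracle():
    """Adjacent-variant dosage r^2 agrees with a brute-force draw of the
    same thresholded-Gaussian latent model."""
    rho, maf = 0.9, 0.3
    cfg = _cfg(n_pairs=10_000, n_variants=2, ld_block_size=2, ld_rho=rho,
               maf_range=(maf, maf))
    ds = simulate_genotypes(cfg)
    r2_sim = np.corrcoef(ds.dosage[:, 0], ds.dosage[:, 1])[0, 1] ** 2

    # oracle: 10^6 independent draws of the identical generative recipe
    orng = np.random.default_rng(99)
    n = 1_000_000
    thr = stats.norm.ppf(maf)
    dose = np.zeros((n, 2))
    for _ in range(2):
        shared = orng.standard_normal(n)
        z1 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * orng.standard_normal(n)
        z2 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * orng.standard_normal(n)
        dose[:, 0] += z1 < thr
        dose[:, 1] += z2 < thr
    r2_oracle = np.corrcoef(dose[:, 0], dose[:, 1])[0, 1] ** 2
    assert abs(r2_sim - r2_oracle) < 0.04


def test_subpopulation_shift_is_visible_in_frequencies():
    cfg = _cfg(n_pairs=4000, n_variants=40, subpop_fraction=0.5,
               subpop_shift=0.3, ld_rho=0.0)
    ds = simulate_genotypes(cfg)
    # allele-frequency spread should exceed binomial noise around the draw
    dev = np.abs(ds.effect_allele_frequency()
                 - ds.variants["allele_frequency"])
    assert dev.mean() > 0.02


# ---------------------------------------------------------------- MZ cohort

def test_mz_members_share_one_genotype_row():
    cfg = _cfg(n_pairs=50, n_variants=20, n_sensitivity_loci=2)
    ds = simulate_genotypes(cfg)
    twins, _ = simulate_mz_cohort(ds, cfg)
    assert len(twins) == 50
    assert twins["genotype_sample_id"].is_unique
    assert set(twins["genotype_sample_id"]) <= set(ds.samples)


def test_no_nonshared_variance_means_perfect_concordance():
    cfg = _cfg(n_pairs=40, n_variants=20, n_sensitivity_loci=0,
               baseline_sensitivity=0.0, noise_sd=0.0)
    ds = simulate_genotypes(cfg)
    twins, _ = simulate_mz_cohort(ds, cfg)
    assert np.allclose(twins["phenotype_a"], twins["phenotype_b"])


def test_discordance_scales_with_genotype_at_sensitivity_locus():
    """Mean |y_A - y_B| per genotype class matches the closed-form
    half-normal expectation |s(g)| * sqrt(2) * nu * sqrt(2/pi)."""
    maf = 0.3
    cfg = _cfg(n_pairs=60_000, n_variants=1, n_sensitivity_loci=1,
               sensitivity_weight=0.5, baseline_sensitivity=1.0,
               nonshared_env_sd=1.0, noise_sd=0.0, shared_env_sd=0.5,
               maf_range=(maf, maf), ld_rho=0.0)
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    twins, _ = simulate_mz_cohort(ds, cfg, truth=truth)
    d = np.abs(twins["phenotype_a"] - twins["phenotype_b"]).to_numpy()
    g = ds.dosage[:, 0]
    p = truth.panel_frequencies[truth.sensitivity_locus_ids[0]]
    for cls in (0.0, 1.0, 2.0):
        mask = g == cls
        s = 1.0 + 0.5 * (cls - 2 * p)
        expect = abs(s) * np.sqrt(2.0) * np.sqrt(2.0 / np.pi)
        obs = d[mask].mean()
        se = d[mask].std() / np.sqrt(mask.sum())
        assert abs(obs - expect) < 4 * se


def test_main_effect_cancels_within_pairs():
    """With zero sensitivity weights, |y_A - y_B| has the same
    distribution in every genotype class of a main-effect locus."""
    cfg = _cfg(n_pairs=3000, n_variants=10, n_main_loci=1, main_weight=2.0,
               n_sensitivity_loci=0, ld_rho=0.0)
    ds = simulate_genotypes(cfg)
    twins, truth = simulate_mz_cohort(ds, cfg)
    d = np.abs(twins["phenotype_a"] - twins["phenotype_b"]).to_numpy()
    j = ds.variant_index()[truth.main_locus_ids[0]]
    g = ds.dosage[:, j]
    groups = [d[g == c] for c in (0, 1, 2) if np.sum(g == c) > 5]
    _, p = stats.kruskal(*groups)
    assert p > 0.001


def test_variance_bookkeeping_with_no_genetics():
    cfg = _cfg(n_pairs=50_000, n_variants=5, shared_env_sd=0.7,
               baseline_sensitivity=1.2, nonshared_env_sd=0.9,
               noise_sd=0.5)
    ds = simulate_genotypes(cfg)
    twins, _ = simulate_mz_cohort(ds, cfg)
    y = np.concatenate([twins["phenotype_a"], twins["phenotype_b"]])
    expected = 0.7**2 + (1.2 * 0.9) ** 2 + 0.5**2
    assert abs(y.var() / expected - 1.0) < 0.03


# ------------------------------------------------------------- validation

def test_rge_zero_means_score_exposure_independence():
    cfg = _cfg(n_unrelated=4000, n_variants=30, n_sensitivity_loci=3,
               rge_coefficient=0.0)
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    val = simulate_validation_cohort(ds, truth, cfg)
    rows = cohort_slices(cfg)["validation"]
    s = truth.true_sensitivity(ds.subset_samples(
        np.arange(rows.start, rows.stop)))
    r = np.corrcoef(s, val["parenting_total"])[0, 1]
    assert abs(r) < 3.0 / np.sqrt(len(val))


def test_rge_coefficient_induces_correlation():
    cfg = _cfg(n_unrelated=4000, n_variants=30, n_sensitivity_loci=3,
               rge_coefficient=0.5)
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    val = simulate_validation_cohort(ds, truth, cfg)
    rows = cohort_slices(cfg)["validation"]
    s = truth.true_sensitivity(ds.subset_samples(
        np.arange(rows.start, rows.stop)))
    assert np.corrcoef(s, val["parenting_total"])[0, 1] > 0.1


def test_crossover_tertile_pattern():
    """High-sensitivity tertile shows a strong positive outcome slope on
    (negative) parenting; the low tertile is nearly flat."""
    cfg = _cfg(n_unrelated=40_000, n_variants=40, n_sensitivity_loci=20,
               sensitivity_weight=0.4, validation_noise_sd=1.0,
               ld_rho=0.0)
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    val = simulate_validation_cohort(ds, truth, cfg)
    rows = cohort_slices(cfg)["validation"]
    s = truth.true_sensitivity(ds.subset_samples(
        np.arange(rows.start, rows.stop)))
    tert = np.digitize(s, np.quantile(s, [1 / 3, 2 / 3]))
    slopes = []
    for t in (0, 2):
        mask = tert == t
        slope = np.polyfit(val["parenting_total"][mask],
                           val["emotional_symptoms"][mask], 1)[0]
        slopes.append(slope)
    low, high = slopes
    assert high > 1.5
    assert abs(low) < 0.5 * high


# -------------------------------------------------------------- treatment

def test_deterministic_limit_reproduces_trajectory():
    cfg = _cfg(n_subjects=60, n_variants=10, n_trials=2,
               subject_sd=0.0, trial_sd=0.0, residual_sd=0.0,
               arm_moderation=(0.0, 0.0, 0.0), missing_rate=0.0,
               n_sensitivity_loci=0, diagnosis_effects=(0, 0, 0, 0, 0))
    ds = simulate_genotypes(cfg)
    truth = draw_truth(ds, cfg)
    rec = simulate_treatment_cohort(ds, truth, cfg)
    a, b, c = cfg.trajectory
    for col, t in [("csr_post", 0), ("csr_3m", 1), ("csr_6m", 2),
                   ("csr_12m", 3)]:
        expected = np.round(rec["csr_baseline"] + a + b * t + c * t * t)
        expected = np.clip(expected, 0, 8)
        assert np.allclose(rec[col], expected)


def test_no_missingness_gives_complete_follow_up():
    cfg = _cfg(n_subjects=80, n_variants=10, missing_rate=0.0)
    ds = simulate_genotypes(cfg)
    rec = simulate_treatment_cohort(ds, draw_truth(ds, cfg), cfg)
    assert rec[["csr_post", "csr_3m", "csr_6m", "csr_12m"]].notna().all().all()


def test_csr_values_stay_on_ordinal_scale():
    cfg = _cfg(n_subjects=300, n_variants=10, residual_sd=3.0)
    ds = simulate_genotypes(cfg)
    rec = simulate_treatment_cohort(ds, draw_truth(ds, cfg), cfg)
    for col in ("csr_post", "csr_3m", "csr_6m", "csr_12m"):
        vals = rec[col].dropna()
        assert ((vals >= 0) & (vals <= 8)).all()
        assert np.allclose(vals, np.round(vals))
    assert (rec["csr_baseline"] >= 4).all()


def test_confounded_allocation_creates_imbalance():
    cfg = _cfg(n_subjects=2000, n_variants=10, confounded_allocation=True)
    ds = simulate_genotypes(cfg)
    rec = simulate_treatment_cohort(ds, draw_truth(ds, cfg), cfg)
    means = rec.groupby("arm")["csr_baseline"].mean()
    assert means["individual"] - means["parent_led"] > 0.3


# ---------------------------------------------------- determinism/fixtures

def test_identical_seed_identical_outputs(small_config):
    a = simulate_genotypes(small_config)
    b = simulate_genotypes(small_config)
    assert np.array_equal(a.dosage, b.dosage, equal_nan=True)
    ta, _ = simulate_mz_cohort(a, small_config)
    tb, _ = simulate_mz_cohort(b, small_config)
    pd.testing.assert_frame_equal(ta, tb)


def test_fixture_roundtrip_and_manifest(tmp_path, small_config, small_world):
    from twinsens.plink import read_plink

    genotypes, truth = small_world
    twins, _ = simulate_mz_cohort(genotypes, small_config, truth=truth)
    manifest = write_fixture_set(genotypes, {"twins": twins}, truth,
                                 tmp_path / "fx")
    # 3 genotype files + 1 table + truth
    assert len(manifest) == 5
    back = read_plink(tmp_path / "fx" / "genotypes")
    assert np.array_equal(back.dosage, genotypes.dosage, equal_nan=True)
    assert back.samples == genotypes.samples

    manifest2 = write_fixture_set(genotypes, {"twins": twins}, truth,
                                  tmp_path / "fx2")
    assert list(manifest["sha256"]) == list(manifest2["sha256"])


def test_truth_file_roundtrip(tmp_path, small_config, small_world):
    from twinsens.simulate import read_truth

    genotypes, truth = small_world
    write_fixture_set(genotypes, {}, truth, tmp_path)
    back = read_truth(tmp_path / "truth.txt")
    assert back.sensitivity_locus_ids == truth.sensitivity_locus_ids
    np.testing.assert_allclose(
        back.true_sensitivity(genotypes), truth.true_sensitivity(genotypes))
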