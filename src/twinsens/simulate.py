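"""Synthetic cohorts with the generative structure the analysis assumes.

Three cohorts are drawn from one shared variant panel:

* an MZ-twin discovery cohort (one genotype row per pair, both members
  share it) whose within-pair phenotype discordance is amplified by
  sensitivity loci;
* an unrelated validation cohort with a parenting exposure and a
  crossover sensitivity x parenting interaction on emotional symptoms;
* a multi-site treatment cohort with curvilinear severity trajectories,
  subject and trial random intercepts, and arm-specific moderation of
  response by sensitivity.

Sensitivity loci scale the non-shared environmental component without any
phenotypic main effect; main-effect loci shift the phenotype mean without
touching sensitivity.  True sensitivity uses allele-frequency-centred
genotypes, ``s_i = s0 + sum_k w_k (g_ik - 2 p_k)``, so that
``baseline_sensitivity`` is the population-mean sensitivity whatever the
allele frequencies.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    ARM_NAMES,
    DIAGNOSES,
    DIAGNOSIS_PROBS,
    SimulationConfig,
)
from .genotypes import GenotypeDataset
from .plink import write_plink

# stage offsets for seed derivation: same config.seed always yields the
# same stream per stage regardless of call order
_STAGE_GENO = 11
_STAGE_TRUTH = 23
_STAGE_MZ = 37
_STAGE_VAL = 41
_STAGE_TRT = 53

_BASES = np.array(["A", "C", "G", "T"])


def _stage_rng(config: SimulationConfig, stage: int,
               rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng([config.seed % (2**31), stage])


@dataclass
class SimulationTruth:
    """Ground truth of the generative model.

    ``sensitivity_locus_ids`` and ``main_locus_ids`` are disjoint variant
    id sets; ``panel_frequencies`` are the drawn (not empirical) effect
    allele frequencies used to centre genotypes when computing s_i.
    """

    sensitivity_locus_ids: list[str]
    sensitivity_weights: np.ndarray
    main_locus_ids: list[str]
    main_weights: np.ndarray
    baseline_sensitivity: float
    panel_frequencies: dict[str, float] = field(default_factory=dict)

    def true_sensitivity(self, genotypes: GenotypeDataset) -> np.ndarray:
        """s_i = s0 + sum_k w_k (g_ik - 2 p_k) for each sample row."""
        return self.baseline_sensitivity + self._centred_effect(
            genotypes, self.sensitivity_locus_ids, self.sensitivity_weights)

    def main_effect(self, genotypes: GenotypeDataset) -> np.ndarray:
        """Additive phenotypic main effect sum_k beta_G (g_ik - 2 p_k)."""
        return self._centred_effect(
            genotypes, self.main_locus_ids, self.main_weights)

    def _centred_effect(self, genotypes: GenotypeDataset, ids: list[str],
                        weights: np.ndarray) -> np.ndarray:
        if not ids:
            return np.zeros(genotypes.n_samples)
        idx = genotypes.variant_index()
        cols, w = [], []
        for vid, wt in zip(ids, weights):
            if vid not in idx:
                raise ValueError(f"truth locus {vid} absent from genotypes")
            j = idx[vid]
            p = self.panel_frequencies.get(vid, np.nan)
            g = genotypes.dosage[:, j].copy()
            g[np.isnan(g)] = 2 * p  # mean-impute rare missing calls
            cols.append(g - 2 * p)
            w.append(wt)
        return np.column_stack(cols) @ np.asarray(w)


def cohort_slices(config: SimulationConfig) -> dict[str, slice]:
    """Row ranges of the shared genotype matrix for the three cohorts."""
    a = config.n_pairs
    b = a + config.n_unrelated
    c = b + config.n_subjects
    return {"pairs": slice(0, a), "validation": slice(a, b),
            "treatment": slice(b, c)}


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Draw the shared genotype matrix for all three cohorts.

    One row per MZ pair (members are genetically identical) followed by one
    row per validation individual and one per trial subject.  Variants sit
    in LD blocks: within a block each haplotype draws equicorrelated latent
    Gaussians (correlation ``ld_rho``) thresholded at the allele-frequency
    quantile; dosage is the sum of two independent haplotypes.
    """
    config.validate()
    rng = _stage_rng(config, _STAGE_GENO, rng)

    m = config.n_variants
    n = config.n_pairs + config.n_unrelated + config.n_subjects

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    # variant metadata: blocks laid contiguously, 50 kb spacing, spread
    # over chromosomes 1..22
    block = np.arange(m) // config.ld_block_size
    chrom = (block % 22) + 1
    position = np.zeros(m, dtype=int)
    for c in range(1, 23):
        mask = chrom == c
        position[mask] = 50_000 * (1 + np.arange(mask.sum()))
    eff_idx = rng.integers(0, 4, size=m)
    oth_idx = (eff_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame({
        "variant_id": [f"snp{i:06d}" for i in range(m)],
        "chromosome": chrom.astype(str),
        "position": position,
        "effect_allele": _BASES[eff_idx],
        "other_allele": _BASES[oth_idx],
        "allele_frequency": maf,
    })

    samples = (
        [f"P{i:05d}" for i in range(config.n_pairs)]
        + [f"V{i:05d}" for i in range(config.n_unrelated)]
        + [f"T{i:05d}" for i in range(config.n_subjects)]
    )

    if m == 0 or n == 0:
        return GenotypeDataset(variants=variants, samples=samples,
                               dosage=np.zeros((n, m)))

    # optional second subpopulation with shifted allele frequencies;
    # membership is deterministic (the first `fraction` of sample rows)
    # so tests and PC diagnostics know the true labels
    is_pop2 = np.arange(n) < int(round(config.subpop_fraction * n))
    shift = rng.uniform(-config.subpop_shift, config.subpop_shift, size=m)
    maf2 = np.clip(maf + shift, 0.01, 0.99)

    rho = config.ld_rho
    thr1 = norm.ppf(maf)
    thr2 = norm.ppf(maf2)
    dosage = np.zeros((n, m))
    for _hap in range(2):
        shared = rng.standard_normal((n, block[-1] + 1))
        z = (np.sqrt(rho) * shared[:, block]
             + np.sqrt(1 - rho) * rng.standard_normal((n, m)))
        thr = np.where(is_pop2[:, None], thr2[None, :], thr1[None, :])
        dosage += (z < thr).astype(float)

    if config.genotype_missing_rate > 0:
        miss = rng.random((n, m)) < config.genotype_missing_rate
        dosage[miss] = np.nan

    return GenotypeDataset(variants=variants, samples=samples, dosage=dosage)


def draw_truth(
    genotypes: GenotypeDataset,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Choose disjoint sensitivity and main-effect locus sets."""
    config.validate()
    if config.n_sensitivity_loci + config.n_main_loci > genotypes.n_variants:
        raise ValueError("more loci requested than variants available")
    rng = _stage_rng(config, _STAGE_TRUTH, rng)
    perm = rng.permutation(genotypes.n_variants)
    sens_idx = perm[: config.n_sensitivity_loci]
    main_idx = perm[config.n_sensitivity_loci:
                    config.n_sensitivity_loci + config.n_main_loci]
    vids = genotypes.variants["variant_id"].to_numpy()
    freqs = genotypes.variants["allele_frequency"].to_numpy()
    return SimulationTruth(
        sensitivity_locus_ids=list(vids[sens_idx]),
        sensitivity_weights=np.full(len(sens_idx),
                                    config.sensitivity_weight),
        main_locus_ids=list(vids[main_idx]),
        main_weights=np.full(len(main_idx), config.main_weight),
        baseline_sensitivity=config.baseline_sensitivity,
        panel_frequencies={v: float(f) for v, f in
                           zip(vids[list(sens_idx) + list(main_idx)],
                               freqs[list(sens_idx) + list(main_idx)])},
    )


def simulate_mz_cohort(
    genotypes: GenotypeDataset,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """MZ-pair phenotypes from the shared genotype rows.

    Member phenotype ``y_ij = main_i + c_i + s_i E_ij + eps_ij`` with the
    shared component c_i per pair and E, eps independent per member.
    Returns (pair table, truth); the pair table has columns pair_id,
    phenotype_a, phenotype_b, age, sex, genotype_sample_id.
    """
    if truth is None:
        truth = draw_truth(genotypes, config)
    rng = _stage_rng(config, _STAGE_MZ, rng)

    rows = cohort_slices(config)["pairs"]
    geno = genotypes.subset_samples(np.arange(rows.start, rows.stop))
    n = geno.n_samples

    s = truth.true_sensitivity(geno)
    main = truth.main_effect(geno)
    c = rng.normal(0.0, config.shared_env_sd, size=n)
    E = rng.normal(0.0, config.nonshared_env_sd, size=(n, 2))
    eps = rng.normal(0.0, config.noise_sd, size=(n, 2))
    y = main[:, None] + c[:, None] + s[:, None] * E + eps

    lo, hi = config.twin_age_range
    cohort = pd.DataFrame({
        "pair_id": [f"pair{i:05d}" for i in range(n)],
        "phenotype_a": y[:, 0],
        "phenotype_b": y[:, 1],
        "age": rng.uniform(lo, hi, size=n),
        "sex": rng.integers(0, 2, size=n),
        "genotype_sample_id": geno.samples,
    })
    return cohort, truth


def simulate_validation_cohort(
    genotypes: GenotypeDataset,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Unrelated cohort with a crossover sensitivity x parenting effect.

    The parenting exposure (higher = more negative parenting) is standard
    normal plus ``rge_coefficient`` times centred sensitivity; the outcome
    is ``main_i + s_i P_i + noise`` so sensitivity has no main effect.
    Positive/negative sub-scales are noisy components of the total, both
    oriented so that higher means more negative parenting.
    """
    rng = _stage_rng(config, _STAGE_VAL, rng)
    rows = cohort_slices(config)["validation"]
    geno = genotypes.subset_samples(np.arange(rows.start, rows.stop))
    n = geno.n_samples

    s = truth.true_sensitivity(geno)
    s_c = s - truth.baseline_sensitivity
    P = rng.standard_normal(n) + config.rge_coefficient * s_c
    y = (truth.main_effect(geno) + s * P
         + rng.normal(0.0, config.validation_noise_sd, size=n))

    half = 1.0 / np.sqrt(2.0)
    neg = half * (P + rng.standard_normal(n))
    pos = half * (P + rng.standard_normal(n))  # reversed positive items

    lo, hi = config.twin_age_range
    return pd.DataFrame({
        "sample_id": geno.samples,
        "emotional_symptoms": y,
        "parenting_total": P,
        "parenting_negative": neg,
        "parenting_positive": pos,
        "ses": rng.standard_normal(n),
        "age": rng.uniform(lo, hi, size=n),
        "sex": rng.integers(0, 2, size=n),
    })


def _allocate_arms(csr0: np.ndarray, age: np.ndarray,
                   config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(csr0)
    if not config.confounded_allocation:
        return rng.integers(0, len(ARM_NAMES), size=n)
    # allocation depends on baseline severity and age only: severe/older
    # children tend toward individual CBT, mild/younger toward parent-led
    # (moderate imbalance, pre-match SMDs ~ 0.5-0.8 on the drivers)
    sev = csr0 - 6.0
    age_c = age - np.mean(config.trial_age_range)
    eta = np.column_stack([
        0.35 * sev + 0.15 * age_c,
        np.zeros(n),
        -0.35 * sev - 0.15 * age_c,
    ])
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (u[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)


def simulate_treatment_cohort(
    genotypes: GenotypeDataset,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multi-site trial cohort with curvilinear CSR trajectories.

    Change at follow-up index t in {0,1,2,3} (post, 3, 6, 12 months)::

        delta_t = a + b t + c t^2 + arm_effect + gamma_arm (s_i - s0)
                  + diagnosis_effect + u_subject + u_trial + eps_t

    CSR_t = clip(round(CSR_0 + delta_t), 0, 8) keeps the ordinal 0-8
    scale.  Follow-ups go missing independently at ``missing_rate``
    (the post-treatment assessment is forced observed so each subject has
    at least one outcome).
    """
    if len(ARM_NAMES) == 0:  # pragma: no cover - defensive
        raise ValueError("arm list is empty")
    rng = _stage_rng(config, _STAGE_TRT, rng)
    rows = cohort_slices(config)["treatment"]
    geno = genotypes.subset_samples(np.arange(rows.start, rows.stop))
    n = geno.n_samples

    s = truth.true_sensitivity(geno)
    s_c = s - truth.baseline_sensitivity

    csr0 = rng.choice([4, 5, 6, 7, 8], size=n,
                      p=[0.25, 0.30, 0.25, 0.15, 0.05])
    lo, hi = config.trial_age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)
    arm_idx = _allocate_arms(csr0.astype(float), age, config, rng)
    diag_idx = rng.choice(len(DIAGNOSES), size=n, p=DIAGNOSIS_PROBS)
    trial = rng.integers(0, config.n_trials, size=n)

    p_int = 1.0 / (1.0 + np.exp(
        -(np.log(0.25 / 0.75) + config.comorbid_confounding * s_c)))
    com_int = (rng.random(n) < p_int).astype(float)
    com_ext = (rng.random(n) < 0.20).astype(float)
    parental = rng.standard_normal(n)

    u_subj = rng.normal(0.0, config.subject_sd, size=n)
    u_trial = rng.normal(0.0, config.trial_sd, size=config.n_trials)
    a, b, c = config.trajectory
    arm_eff = np.asarray(config.arm_effects)[arm_idx]
    gamma = np.asarray(config.arm_moderation)[arm_idx]
    diag_eff = np.asarray(config.diagnosis_effects)[diag_idx]

    t = np.arange(4)
    delta = (
        a + b * t[None, :] + c * t[None, :] ** 2
        + (arm_eff + gamma * s_c + diag_eff
           + config.comorbid_effect * com_int
           + u_subj + u_trial[trial])[:, None]
        + rng.normal(0.0, config.residual_sd, size=(n, 4))
    )
    csr_t = np.clip(np.round(csr0[:, None] + delta), 0, 8)

    observed = rng.random((n, 4)) >= config.missing_rate
    observed[:, 0] = True  # post-treatment always assessed
    csr_t = np.where(observed, csr_t, np.nan)

    miss_com = rng.random(n) < config.comorbid_missing_rate
    miss_par = rng.random(n) < config.parental_missing_rate
    com_int[miss_com] = np.nan
    com_ext[miss_com] = np.nan
    parental[miss_par] = np.nan

    return pd.DataFrame({
        "subject_id": geno.samples,
        "trial_id": [f"trial{k}" for k in trial],
        "arm": [ARM_NAMES[k] for k in arm_idx],
        "primary_diagnosis": [DIAGNOSES[k] for k in diag_idx],
        "age": age,
        "sex": sex,
        "csr_baseline": csr0,
        "csr_post": csr_t[:, 0],
        "csr_3m": csr_t[:, 1],
        "csr_6m": csr_t[:, 2],
        "csr_12m": csr_t[:, 3],
        "comorbid_internalizing": com_int,
        "comorbid_externalizing": com_ext,
        "parental_psychopathology": parental,
    })


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    genotypes: GenotypeDataset,
    tables: dict[str, pd.DataFrame],
    truth: SimulationTruth,
    directory: str | os.PathLike,
) -> pd.DataFrame:
    """Write genotypes (PLINK triple), cohort TSVs and the truth file.

    Returns a manifest DataFrame (file name, sha256) also written to
    ``manifest.tsv`` in the directory.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = write_plink(genotypes, os.path.join(directory, "genotypes"))

    for name, table in tables.items():
        path = os.path.join(directory, f"{name}.tsv")
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths.append(path)

    truth_path = os.path.join(directory, "truth.txt")
    with open(truth_path, "w") as fh:
        fh.write(f"baseline_sensitivity\t{truth.baseline_sensitivity:.10g}\n")
        for vid, w in zip(truth.sensitivity_locus_ids,
                          truth.sensitivity_weights):
            p = truth.panel_frequencies.get(vid, float("nan"))
            fh.write(f"sensitivity_locus\t{vid}\t{w:.10g}\t{p:.10g}\n")
        for vid, w in zip(truth.main_locus_ids, truth.main_weights):
            p = truth.panel_frequencies.get(vid, float("nan"))
            fh.write(f"main_locus\t{vid}\t{w:.10g}\t{p:.10g}\n")
    paths.append(truth_path)

    manifest = pd.DataFrame({
        "file": [os.path.basename(p) for p in paths],
        "sha256": [_sha256(p) for p in paths],
    })
    manifest.to_csv(os.path.join(directory, "manifest.tsv"),
                    sep="\t", index=False)
    return manifest


def read_truth(path: str | os.PathLike) -> SimulationTruth:
    """Read a truth file written by :func:`write_fixture_set`."""
    s0 = 0.0
    sens_ids: list[str] = []
    sens_w: list[float] = []
    main_ids: list[str] = []
    main_w: list[float] = []
    freqs: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "baseline_sensitivity":
                s0 = float(parts[1])
            elif parts[0] == "sensitivity_locus":
                sens_ids.append(parts[1])
                sens_w.append(float(parts[2]))
                freqs[parts[1]] = float(parts[3])
            elif parts[0] == "main_locus":
                main_ids.append(parts[1])
                main_w.append(float(parts[2]))
                freqs[parts[1]] = float(parts[3])
    return SimulationTruth(
        sensitivity_locus_ids=sens_ids,
        sensitivity_weights=np.asarray(sens_w),
        main_locus_ids=main_ids,
        main_weights=np.asarray(main_w),
        baseline_sensitivity=s0,
        panel_frequencies=freqs,
    )
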