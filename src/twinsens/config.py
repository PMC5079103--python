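"""Simulation and pipeline configuration.

The defaults describe the study conditions the package emulates: a
~1,000-pair MZ discovery cohort, a ~1,400-child validation cohort with a
parenting exposure, and a ~900-subject multi-site CBT trial sample with
three treatment arms of decreasing intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

ARM_NAMES = ("individual", "group", "parent_led")
DIAGNOSES = ("GAD", "social", "specific_phobia", "separation", "other")
#: baseline primary-diagnosis mix of the trial sample
DIAGNOSIS_PROBS = (0.372, 0.207, 0.109, 0.229, 0.083)


class ConfigError(ValueError):
    """A simulation-config field failed validation."""


@dataclass
class SimulationConfig:
    """Generative parameters for all three synthetic cohorts.

    Phenotype model for twin j of pair i::

        y_ij = sum_k beta_G g_ik + c_i + s_i * E_ij + eps_ij
        s_i  = s0 + sum_k w_k (g_ik - 2 p_k)

    with c_i shared per pair, E_ij ~ N(0, nonshared_env_sd^2) and
    eps_ij ~ N(0, noise_sd^2) independent per member.  Sensitivity loci
    carry no phenotypic main effect (the differential-susceptibility
    ideal); main-effect loci carry no sensitivity weight.
    """

    # cohort sizes
    n_pairs: int = 1000
    n_unrelated: int = 1400
    n_subjects: int = 900
    n_trials: int = 5

    # genotype panel
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.7
    genotype_missing_rate: float = 0.0
    # optional two-subpopulation allele-frequency shift (for PC tests)
    subpop_fraction: float = 0.0
    subpop_shift: float = 0.0

    # genetic architecture
    n_sensitivity_loci: int = 20
    sensitivity_weight: float = 0.4
    n_main_loci: int = 10
    main_weight: float = 0.1
    baseline_sensitivity: float = 1.0

    # twin phenotype variance components (composite z-score units)
    shared_env_sd: float = 0.7
    nonshared_env_sd: float = 1.0
    noise_sd: float = 1.0

    # validation cohort: outcome noise sets the G x E interaction share
    # Var(s_c)/Var(y); the default puts it near 0.5% of outcome variance
    validation_noise_sd: float = 15.2
    rge_coefficient: float = 0.0

    # treatment cohort
    arm_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    arm_moderation: tuple[float, float, float] = (-0.5, 0.0, 0.5)
    trajectory: tuple[float, float, float] = (-2.0, -0.5, 0.08)
    diagnosis_effects: tuple[float, ...] = (0.0, 0.43, 0.19, 0.0, 0.0)
    subject_sd: float = 0.8
    trial_sd: float = 0.3
    residual_sd: float = 1.0
    missing_rate: float = 0.1
    confounded_allocation: bool = False
    comorbid_missing_rate: float = 0.05
    parental_missing_rate: float = 0.10
    # optional confounding of comorbid internalizing disorder with
    # sensitivity (log-odds per unit s) and with response (CSR-change units)
    comorbid_confounding: float = 0.0
    comorbid_effect: float = 0.0

    # demographics
    twin_age_range: tuple[float, float] = (10.9, 11.6)
    trial_age_range: tuple[float, float] = (6.0, 14.0)

    seed: int = 0

    def validate(self) -> "SimulationConfig":
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"invalid {name}: {why}")

        for name in ("n_pairs", "n_unrelated", "n_subjects", "n_variants",
                     "n_sensitivity_loci", "n_main_loci"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        if self.n_trials < 1:
            raise bad("n_trials", "must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise bad("maf_range", "bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.ld_block_size < 1:
            raise bad("ld_block_size", "must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise bad("ld_rho", "must be in [0, 1)")
        if self.n_sensitivity_loci + self.n_main_loci > self.n_variants:
            raise bad("n_sensitivity_loci",
                      "sensitivity + main loci exceed n_variants")
        for name in ("shared_env_sd", "nonshared_env_sd", "noise_sd",
                     "validation_noise_sd", "subject_sd", "trial_sd",
                     "residual_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "standard deviation must be >= 0")
        for name in ("missing_rate", "genotype_missing_rate",
                     "subpop_fraction", "comorbid_missing_rate",
                     "parental_missing_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise bad(name, "must be a probability in [0, 1]")
        if self.baseline_sensitivity < 0:
            raise bad("baseline_sensitivity", "must be >= 0")
        if len(self.arm_effects) != len(ARM_NAMES):
            raise bad("arm_effects", f"needs {len(ARM_NAMES)} entries")
        if len(self.arm_moderation) != len(ARM_NAMES):
            raise bad("arm_moderation", f"needs {len(ARM_NAMES)} entries")
        if len(self.diagnosis_effects) != len(DIAGNOSES):
            raise bad("diagnosis_effects", f"needs {len(DIAGNOSES)} entries")
        if len(self.trajectory) != 3:
            raise bad("trajectory", "needs (intercept, linear, quadratic)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        return cfg.validate()


@dataclass
class QcThresholds:
    """Per-SNP inclusion thresholds: call rate, MAF and HWE exact p."""

    min_call_rate: float = 0.98
    min_maf: float = 0.01
    min_hwe_p: float = 1e-20

    def validate(self) -> "QcThresholds":
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"invalid {name}: must be in [0, 1]")
        return self


#: discovery-cohort preset (array-genotyped population twin sample)
DISCOVERY_QC = QcThresholds(min_call_rate=0.98, min_maf=0.01, min_hwe_p=1e-20)
#: treatment-cohort preset (clinical trial sample, stricter call/MAF)
TREATMENT_QC = QcThresholds(min_call_rate=0.99, min_maf=0.05, min_hwe_p=1e-5)


@dataclass
class ClumpParameters:
    """p-value-informed LD clumping settings (r^2 cutoff, +/- window in kb)."""

    r2_threshold: float = 0.25
    window_kb: float = 200.0
    p_field: str = "p"

    def validate(self) -> "ClumpParameters":
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ConfigError("invalid r2_threshold: must be in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigError("invalid window_kb: must be > 0")
        return self


#: the eight p-value cutoffs of the score threshold sweep
DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def validate_thresholds(thresholds: Sequence[float]) -> tuple[float, ...]:
    t = tuple(float(x) for x in thresholds)
    if not t:
        raise ConfigError("invalid thresholds: empty")
    if any(not (0.0 < x <= 1.0) for x in t):
        raise ConfigError("invalid thresholds: each must be in (0, 1]")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ConfigError("invalid thresholds: must be strictly increasing")
    return t
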