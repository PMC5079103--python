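import numpy as np
import pytest

from twinsens import SimulationConfig, simulate_genotypes, draw_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small all-cohort configuration used by several integration tests."""
    return SimulationConfig(
        n_pairs=120, n_unrelated=150, n_subjects=120, n_trials=3,
        n_variants=60, n_sensitivity_loci=5, n_main_loci=3, seed=11,
    ).validate()


@pytest.fixture(scope="session")
def small_world(small_config):
    """(genotypes, truth) pair shared across read-only tests."""
    genotypes = simulate_genotypes(small_config)
    truth = draw_truth(genotypes, small_config)
    return genotypes, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
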