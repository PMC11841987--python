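from dataclasses import replace

import numpy as np
import pytest

from fearcond.pipeline import score_cohort
from fearcond.synthetic import SimulationConfig, calibrate_ctq_multiplier, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def ctq_multiplier(default_config) -> float:
    return calibrate_ctq_multiplier(default_config)


@pytest.fixture(scope="session")
def small_cohort(default_config, ctq_multiplier):
    """n=120 cohort with ratings, amplitude mode."""
    cfg = replace(default_config, n=120)
    return generate_cohort(cfg, seed=11, ctq_multiplier=ctq_multiplier)


@pytest.fixture(scope="session")
def small_amplitudes(small_cohort):
    return score_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
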