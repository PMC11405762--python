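import numpy as np
import pytest

from imiomics_cpet.config import CohortConfig, GridSpec, RegistrationConfig


def small_grid() -> GridSpec:
    """Half-resolution grid covering the same physical extents as the
    default desk grid; keeps registration-heavy tests fast."""
    return GridSpec(shape=(32, 24, 64), spacing=(8.0, 8.0, 16.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def noise_free_config() -> CohortConfig:
    cfg = CohortConfig(n_male=2, n_female=2, seed=7)
    cfg.noise.vo2_ml_min = 0.0
    cfg.noise.vco2_ml_min = 0.0
    cfg.noise.ve_l_min = 0.0
    cfg.noise.hr_bpm = 0.0
    return cfg


@pytest.fixture
def small_config() -> CohortConfig:
    return CohortConfig(n_male=3, n_female=3, seed=5, grid=small_grid())


@pytest.fixture
def fast_registration() -> RegistrationConfig:
    return RegistrationConfig(iterations=(40, 20, 6))
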