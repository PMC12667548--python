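import numpy as np
import pytest

from painsense import simcohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast default-knob cohort for plumbing tests."""
    cfg = simcohort.SimulationConfig(n_participants=60, grid_shape=(8, 8, 8),
                                     seed=7)
    return simcohort.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """High-SNR cohort where the multivariate signal is easy to decode."""
    cfg = simcohort.SimulationConfig(
        n_participants=300, grid_shape=(10, 10, 10), seed=0,
        explainable_r2=0.25, signal_voxel_r2=0.95,
        smoothness_fwhm=1.0, pattern_density=0.3)
    return simcohort.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
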