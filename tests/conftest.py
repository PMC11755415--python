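import numpy as np
import pytest

from pulseguard.signal_sim import SimConfig, make_dataset, simulate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A tiny 3-subject cohort for fast end-to-end tests."""
    return SimConfig(n_subjects=3, duration_s=12.0, fs=50.0,
                     hr_range=(60.0, 90.0), noise_sd=0.02,
                     coupling_strength=1.0, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_dataset(small_config, window_s=4.0, stride_s=4.0)


@pytest.fixture(scope="session")
def small_record(small_config):
    return simulate_record(small_config, 0)
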