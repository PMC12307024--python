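import numpy as np
import pytest
from hypothesis import settings

from rifteeg import SimConfig, default_montage, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Single noiseless trial per condition: pure tagged sources."""
    return SimConfig(n_participants=1, n_trials_per_condition=1,
                     noise_sd=0.0, alpha_amp=0.0, participant_sigma=0.0,
                     g_related=0.5, g_unrelated=0.5, seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    """Small noisy dataset for integration-style tests."""
    return SimConfig(n_participants=6, n_trials_per_condition=8, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
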