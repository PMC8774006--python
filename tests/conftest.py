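import numpy as np
import pytest
from hypothesis import settings

from nftrial.config import SessionDesign, SessionModel, TrialConfig

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_design():
    """Two-cycle session at 5 Hz: fast enough for per-test simulation."""
    return SessionDesign(rest_s=30.0, task_s=60.0, n_cycles=2, fs=5.0)


@pytest.fixture
def quiet_model():
    """Noise-free session model: only drift-free systemic + neural term."""
    return SessionModel(drift_slope_sd=0.0, motion_rate_per_min=0.0,
                        white_sd=0.0, short_white_sd=0.0, gain_sd=0.0)


@pytest.fixture
def trial_config():
    return TrialConfig(seed=99)
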