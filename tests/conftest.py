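import numpy as np
import pytest
from hypothesis import settings

from gdnet.synthetic import SyntheticConfig, build_stimulus_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def table40():
    return build_stimulus_table(40)


@pytest.fixture
def tiny_cfg():
    """Small, fast synthetic configuration for unit tests."""
    return SyntheticConfig(n_channels=4, trial_duration=1.0, n_harmonics=2,
                           snr_db=10.0, n_trials_per_class=2, seed=7)
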