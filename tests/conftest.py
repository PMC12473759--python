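import numpy as np
import pytest
from hypothesis import settings

from astw.synthetic_data import SynthConfig, generate_trial

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cfg():
    """Short-segment generator config for fast structural tests."""
    return SynthConfig(seed=7, n_trials=2, movement_ms=600.0, rest_ms=600.0)


@pytest.fixture(scope="session")
def tiny_trial(tiny_cfg):
    return generate_trial(tiny_cfg, subject=0, trial=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
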