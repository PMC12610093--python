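import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stcca import nn
from stcca.synthetic import SynthConfig, generate_trialset


@pytest.fixture
def small_trialset():
    """Four classes, 8 channels, 1 s at 256 Hz, 5 trials per class."""
    return generate_trialset(SynthConfig(trials_per_class=5, seed=42))


@pytest.fixture
def float64_params():
    """Build network parameters in float64 for high-precision checks."""
    nn.set_default_dtype(np.float64)
    yield
    nn.set_default_dtype(np.float32)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
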