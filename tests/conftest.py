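import numpy as np
import pytest

from jrnmm import ModelParameters, get_preset


@pytest.fixture(scope="session")
def params():
    """Standard parameter set at connectivity scale C = 135."""
    return ModelParameters.from_C(135.0)


@pytest.fixture(scope="session")
def alpha_inputs():
    """Noisy alpha-rhythm inputs: mu = (0, 220, 0), sigma = (10, 1000, 10)."""
    return get_preset("alpha_C135").inputs()


@pytest.fixture(scope="session")
def quiet_inputs(alpha_inputs):
    """Same forcing with the noise switched off."""
    return alpha_inputs.with_sigma(0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
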