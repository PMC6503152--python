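import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcdcm.circuit import CircuitParameters
from tcdcm.forward import default_freqs
from tcdcm.model_space import winning_spec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def params():
    return CircuitParameters.defaults()


@pytest.fixture
def winning():
    return winning_spec()


@pytest.fixture
def freqs():
    return default_freqs()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
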