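import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: fixed seed for every stochastic check in the suite
SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
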