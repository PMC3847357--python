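import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_example():
    """Parameters of the two-treatment worked scenario used throughout."""
    return {
        "n": 2500,
        "deaths": 750,
        "u_b": (0.5, 0.6),
        "u_t": (0.8, 0.8),
        "rrr": (0.07, 0.1),
        "rr": (0.93, 0.90),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
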