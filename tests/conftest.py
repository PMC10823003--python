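import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, d, scale=1.0):
    """Well-conditioned random SPD matrix of side d."""
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))


@pytest.fixture
def spd_factory(rng):
    return lambda d, scale=1.0: random_spd(rng, d, scale)
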