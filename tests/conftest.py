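import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_quaternions(rng, n):
    """Haar-uniform unit quaternions (normalized 4-D Gaussians)."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture
def random_q():
    return random_quaternions
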