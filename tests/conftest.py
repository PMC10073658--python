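import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """Random 9-frame 24x30 uint8 stack for descriptor tests."""
    from cageclimb import FrameStack

    return FrameStack(rng.integers(0, 256, size=(9, 24, 30)).astype(np.uint8))
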