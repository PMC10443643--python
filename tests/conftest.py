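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
def short_tilting_kwargs():
    """Shortened tilting protocol for fast end-to-end tests."""
    return dict(
        supine1_s=120.0,
        trendelenburg_s=120.0,
        supine2_s=60.0,
        transition_range_s=(10.0, 20.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
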