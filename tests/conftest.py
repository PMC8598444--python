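import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _silence_small_R_warning():
    """Small-R CLT warnings are expected on toy fixtures; keep test output clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*normal approximation may be poor.*"
        )
        warnings.filterwarnings("ignore", message=".*clamping to a single region.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
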