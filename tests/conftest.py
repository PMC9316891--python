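import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from forcequant import SynthesisSpec, generate_forcing

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def season100():
    """One 100-day growing-season realization shared across the suite."""
    return generate_forcing(SynthesisSpec(n_days=100, seed=1))


@pytest.fixture()
def tiny_season():
    """A fast 4-day realization for structural tests."""
    return generate_forcing(SynthesisSpec(n_days=4, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
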