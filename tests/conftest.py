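import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainrecov import Reference, ReferenceSpec, generate_reference

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    """A 10 kb reference genome shared by cheap unit tests."""
    return generate_reference(ReferenceSpec("spTest", 10_000, seed=42))
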