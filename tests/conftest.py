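import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amplihap import generate_reference

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    """A 300-base random amplicon reference shared across tests."""
    return generate_reference(300, gc_fraction=0.5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
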