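import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tapnet.simulate import SimConfig, simulate_cascade  # noqa: E402


@pytest.fixture(scope="session")
def small_study():
    """A 300-gene synthetic study shared by read-only tests."""
    return simulate_cascade(SimConfig(n_genes=300, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
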