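import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)


@pytest.fixture
def small_instance():
    """A fixed small (cache, pars) instance exercised by several modules."""
    import lspaint as lp

    return lp.random_instance(12345, n_range=(8, 8), l_range=(12, 12))
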