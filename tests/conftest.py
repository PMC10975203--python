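import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_orchard():
    """A 12-tree two-epoch orchard shared by growth/density tests."""
    from crowngrowth import generate_orchard

    return generate_orchard(n_trees=12, seed=20240301)
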