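import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tree():
    from orthospace import TreeParams, simulate_tree

    return simulate_tree(TreeParams(depth=2, length=50, p_b=0.2, seed=7))


@pytest.fixture(scope="session")
def two_tree_pool():
    """Two independently rooted simulated gene families (well separated)."""
    from orthospace import simulate_cluster_pool

    return simulate_cluster_pool(2, depth=3, length=400, p_b=0.05, seed=11)


@pytest.fixture(scope="session")
def three_tree_pool():
    from orthospace import simulate_cluster_pool

    return simulate_cluster_pool(3, depth=3, length=400, p_b=0.05, seed=13)
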