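import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n_max=50, p_edge=None):
    """Random (adjacency, types) pair for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.random()) if p_edge is None else p_edge
    upper = np.triu(rng.random((n, n)) < p, k=1)
    adj = (upper | upper.T).astype(np.uint8)
    types = rng.integers(0, 2, n).astype(np.int8)
    return adj, types
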