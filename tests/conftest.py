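import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_bank():
    """A small bank of deterministic phantoms shared across tests."""
    from topotube.phantom import PhantomSpec, generate_tree

    return [
        generate_tree(PhantomSpec(seed=900 + i, n_loops=i % 4)) for i in range(6)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
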