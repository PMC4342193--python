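import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popgenkit.fixtures import SimSpec, simulate

settings.register_profile(
    "fast",
    max_examples=40,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def small_dataset():
    """17 samples x 5 variants with missingness (exercises byte padding)."""
    return simulate(SimSpec(n_samples=17, n_variants=5, missing_rate=0.1, seed=7))[0]


@pytest.fixture(scope="session")
def medium_dataset():
    """50 samples x 200 variants, 5% missing calls."""
    return simulate(
        SimSpec(n_samples=50, n_variants=200, missing_rate=0.05, seed=11)
    )[0]


@pytest.fixture(scope="session")
def ld_dataset():
    """Blocked-LD fixture: two tight 10-variant blocks among noise."""
    return simulate(
        SimSpec(
            n_samples=120,
            n_variants=60,
            maf_min=0.15,
            ld_blocks=((10, 0.95), (10, 0.9)),
            seed=23,
        )
    )[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dosages(rng, m, n, missing_rate=0.1):
    g = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    if missing_rate:
        g[rng.random((m, n)) < missing_rate] = -1
    return g
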