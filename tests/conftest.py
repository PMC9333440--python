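import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import xpars

settings.register_profile(
    "det", derandomize=True,
    suppress_health_check=[HealthCheck.differing_executors],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def spec_1d():
    return xpars.spec_1d_4feature()


@pytest.fixture(scope="session")
def spec_2d():
    return xpars.spec_2d_8feature()


@pytest.fixture(scope="session")
def planted_1d(spec_1d):
    return xpars.make_planted_model(spec_1d)


@pytest.fixture(scope="session")
def cohort_1d(planted_1d):
    """Mid-sized planted cohort shared across tests."""
    return xpars.simulate_cohort(planted_1d, n=8000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def all_valid_matrices(shape, n_levels):
    """Exhaustive enumeration of valid gene matrices (test oracle)."""
    out = []
    for flat in itertools.product(range(1, n_levels + 1),
                                  repeat=shape[0] * shape[1]):
        g = np.array(flat, dtype=np.int64).reshape(shape)
        if xpars.is_valid(g, n_levels):
            out.append(g)
    return out


def random_valid_chromosome(rng, shape, n_levels):
    """Random valid matrix: cumulative max of uniform draws along both axes."""
    g = rng.integers(1, n_levels + 1, size=shape)
    g = np.maximum.accumulate(g, axis=0)
    g = np.maximum.accumulate(g, axis=1)
    return np.minimum(g, n_levels)
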