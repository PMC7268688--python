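import numpy as np
import pytest

from volcov import CohortConfig, load_region_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_region_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort():
    """22-subject default cohort, fixed seed."""
    from volcov import generate_cohort

    return generate_cohort(CohortConfig(seed=7))


def random_adjacency(rng, n, p=0.4):
    """Random symmetric binary adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1).astype(int)
    return a + a.T
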