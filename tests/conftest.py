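import numpy as np
import pytest

import signedconn as sc


@pytest.fixture(scope="session")
def parcellation_small():
    return sc.make_parcellation(60, 6, seed=1)


@pytest.fixture(scope="session")
def cohort_small():
    cfg = sc.SimulationConfig(n_subjects=15, n_nodes=40, n_modules=6, seed=7)
    return sc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, density=0.6, signed=False):
    """Random symmetric weighted matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if signed:
        w *= rng.choice([-1.0, 1.0], size=(n, n), p=[0.3, 0.7])
    keep = rng.random((n, n)) < density
    w = np.triu(w * keep, 1)
    w = w + w.T
    return w
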