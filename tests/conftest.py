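import numpy as np
import pytest

from manecc import (CohortConfig, simulate_cohort, simulate_parcellation,
                    subject_intercepts)


@pytest.fixture(scope="session")
def parcels_small():
    """60 cortical + 4 subcortical parcels; enough for all stratifications."""
    return simulate_parcellation(n_cortical=60, n_subcortical=4, seed=5)


@pytest.fixture(scope="session")
def parcels_cortical_only():
    return simulate_parcellation(n_cortical=60, n_subcortical=0, seed=5)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_subjects=20, n_cortical=60, n_subcortical=4, seed=9)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_intercepts(small_config):
    return subject_intercepts(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connectome(rng, n=20, density=1.0, log=True):
    """Random symmetric nonnegative zero-diagonal test connectome."""
    from manecc import Connectome
    w = rng.uniform(0.1, 2.0, (n, n))
    w = 0.5 * (w + w.T)
    if density < 1.0:
        mask = rng.uniform(size=(n, n)) < density
        mask = mask | mask.T
        w = w * mask
    np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, parcel_ids=np.arange(n), log_transformed=log)
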