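import numpy as np
import pandas as pd
import pytest

from connica.parcellation import make_parcellation
from connica.simulate import CohortConfig, generate_cohort

SMALL_GROUPS = {"HC": 5, "PD-CN": 5, "PD-MCI": 6}


@pytest.fixture(scope="session")
def parcellation30():
    """Smallest default parcellation: 14 cortical parcels + 16 subcortical."""
    return make_parcellation(30)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-subject, 30-ROI cohort with a planted group effect."""
    return generate_cohort(
        CohortConfig(group_sizes=dict(SMALL_GROUPS), n_rois=30, n_traits=3, seed=42)
    )


@pytest.fixture(scope="session")
def small_group_matrix(small_cohort):
    return small_cohort.group_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric_unit_diag(n, rng):
    """A random valid FC-like matrix (symmetric, unit diagonal, |r| < 1)."""
    a = rng.uniform(-0.9, 0.9, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


def design_from_cohort(cohort) -> pd.DataFrame:
    return cohort.design_frame()
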