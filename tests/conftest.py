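import numpy as np
import pytest

import patsim as ps


@pytest.fixture(scope="session")
def copd_cohort_small():
    """1500-patient COPD-like cohort shared across tests."""
    return ps.generate_cohort(ps.copd_spec(m=1500, seed=11))


@pytest.fixture(scope="session")
def copd_cohort_large():
    """Cohort at the published size, for marginal-fidelity and split checks."""
    return ps.generate_cohort(ps.copd_spec(m=30467, seed=7))


@pytest.fixture(scope="session")
def copd_split(copd_cohort_small):
    return ps.split_train_test(copd_cohort_small, fraction=0.75, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
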