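import numpy as np
import pytest

from thoughtnet import CohortConfig, simulate_cohort, simulate_retest


@pytest.fixture(scope="session")
def desk_cohort():
    """Default desk-scale cohort (200 subjects, 60 nodes, seed 11)."""
    return simulate_cohort(CohortConfig.desk(seed=11))


@pytest.fixture(scope="session")
def desk_retest(desk_cohort):
    return simulate_retest(desk_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
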