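import numpy as np
import pytest

from ctsib_sway import CohortConfig, SwaySimConfig, simulate_cohort, write_fixture
from ctsib_sway.simulate import cohort_index_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (n=27), path lengths only."""
    return simulate_cohort(SwaySimConfig(), CohortConfig(n_participants=27, seed=1234))


@pytest.fixture(scope="session")
def default_index_table(default_cohort):
    return cohort_index_table(default_cohort.sway)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A 3-participant cohort written to disk in the interchange formats."""
    cohort = simulate_cohort(
        SwaySimConfig(), CohortConfig(n_participants=3, seed=7), keep_traces=True
    )
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(cohort, d)
    return d, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)
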