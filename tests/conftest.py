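import numpy as np
import pytest

from vetri import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20200716)


@pytest.fixture(scope="session")
def cohort_specs():
    return fixtures.load_cohort_specs()


@pytest.fixture(scope="session")
def claimed_panel():
    return fixtures.load_claimed_panel()


@pytest.fixture(scope="session")
def outside_table():
    return fixtures.load_outside_percentages()
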