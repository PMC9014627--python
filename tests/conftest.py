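import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trialadjust as ta

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_counts():
    return ta.fixture_table2()


@pytest.fixture(scope="session")
def table2_data(table2_counts):
    return ta.expand_counts(table2_counts, "stratum")


@pytest.fixture(scope="session")
def appendix():
    return ta.fixture_appendix_table5()


@pytest.fixture(scope="session")
def appendix_full(appendix):
    return ta.expand_counts(appendix.full, "x")


@pytest.fixture(scope="session")
def appendix_cc(appendix):
    return ta.expand_counts(appendix.complete_case, "x")


def random_counts(rng, k_max=3, n_max=40):
    """Random small stratified table with every cell non-degenerate."""
    k = rng.integers(1, k_max + 1)
    events = rng.integers(1, n_max, size=(k, 2))
    nonevents = rng.integers(1, n_max, size=(k, 2))
    return ta.StratifiedCounts(list(range(k)), events, nonevents)


@pytest.fixture
def rng():
    return np.random.default_rng(20220418)
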