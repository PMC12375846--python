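import numpy as np
import pytest

from prostasim.defaults import default_economic_config, default_test_profiles
from prostasim.natural_history import NaturalHistoryParams, simulate_cohort
from prostasim.synthetic import make_life_table


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def params():
    return NaturalHistoryParams()


@pytest.fixture(scope="session")
def small_cohort(params, life_table):
    """5,000-person natural-course cohort shared across tests."""
    return simulate_cohort(params, life_table, n=5_000, seed=42)


@pytest.fixture(scope="session")
def mid_cohort(params, life_table):
    """50,000-person cohort for distribution-level checks."""
    return simulate_cohort(params, life_table, n=50_000, seed=4242)


@pytest.fixture(scope="session")
def test_profiles():
    return default_test_profiles()


@pytest.fixture()
def econ_config():
    return default_economic_config()
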