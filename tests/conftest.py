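import pytest

from bwspref.design import statin_outcome_design, default_catalog
from bwspref.synthetic_data import (
    simulate_bws_responses,
    simulate_profiles,
    study_utilities,
)


@pytest.fixture(scope="session")
def design13():
    """The (13, 4, 1) choice-set design on the statin outcome catalog."""
    return statin_outcome_design()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def util_total():
    """Utility configuration from the published total-population coefficients."""
    return study_utilities("total")


@pytest.fixture(scope="session")
def small_dataset(design13, util_total):
    """A 200-respondent simulated survey, reused by read-only tests."""
    profiles = simulate_profiles(200, stratum="urban", seed=42)
    return simulate_bws_responses(design13, util_total, profiles, seed=42)
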