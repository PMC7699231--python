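import pytest

from plastexpo import (
    default_factors,
    filter_for_exposure,
    generate_survey,
)


@pytest.fixture(scope="session")
def survey():
    """The default synthetic survey (3345 products), generated once."""
    return generate_survey(seed=1)


@pytest.fixture(scope="session")
def filtered_survey(survey):
    """Survey after the >100 mg/kg detected-inclusion filter."""
    return filter_for_exposure(survey)


@pytest.fixture(scope="session")
def factors():
    """The calibrated default child factor preset."""
    return default_factors()
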