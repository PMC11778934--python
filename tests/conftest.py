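import pytest

from valsampsize import (
    BinaryValidationDesign,
    ContinuousValidationDesign,
    LPDistribution,
)


@pytest.fixture(scope="session")
def covid_lp():
    """Predicted-risk distribution of the covid-19 deterioration example."""
    return LPDistribution.from_beta(1.33, 1.75)


@pytest.fixture(scope="session")
def covid_design(covid_lp):
    """Binary worked example: prevalence 0.43, c 0.77, beta(1.33, 1.75)."""
    return BinaryValidationDesign(
        prevalence=0.43,
        cstat=0.77,
        lp=covid_lp,
        ciw_oe=0.22,
        ciw_slope=0.3,
        ciw_cstat=0.1,
        ciw_snb=0.2,
        thresholds=(0.1, 0.3),
    )


@pytest.fixture(scope="session")
def pain_design():
    """Continuous worked example: pain intensity, R² 0.40, SD 22.30."""
    return ContinuousValidationDesign(
        r_squared=0.40,
        var_y=497.29,
        ciw_r2=0.1,
        ciw_citl=5.0,
        ciw_slope=0.3,
        mean_y=50.0,
    )
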