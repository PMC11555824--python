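import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from fiscalbod.model_inputs import (  # noqa: E402
    BMICategory,
    FiscalParams,
    ModifierSet,
    PopulationStratum,
    Sex,
)
from fiscalbod.synthetic_data import japan_like_fixture  # noqa: E402


def make_stratum(**overrides) -> PopulationStratum:
    """A valid single stratum with convenient defaults for unit tests."""
    base = dict(
        age_lo=40,
        age_hi=44,
        sex=Sex.male,
        count=100.0,
        bmi_proportions={
            BMICategory.underweight: 0.1,
            BMICategory.normal: 0.7,
            BMICategory.overweight: 0.15,
            BMICategory.obese: 0.05,
        },
        emp_ft=0.6,
        emp_pt=0.1,
        income_ft=100.0,
        income_pt=40.0,
        sickleave_rate=0.05,
        retirement_rate=0.0,
        mepc=10.0,
        mortality_rate=0.01,
    )
    base.update(overrides)
    return PopulationStratum(**base)


@pytest.fixture(scope="session")
def fixture_set():
    """The fixed Japan-like synthetic calibration (strata, modifiers, fiscal, life tables)."""
    return japan_like_fixture()


@pytest.fixture()
def toy_fiscal() -> FiscalParams:
    return FiscalParams(
        tax_wedge=0.3,
        vat_rate=0.1,
        pension_benefit=10.0,
        sickpay_fraction=2.0 / 3.0,
        discount_rate=0.02,
        wage_growth=0.02,
        prevalence_growth={Sex.male: 0.0147, Sex.female: 0.0047},
    )


@pytest.fixture()
def toy_modifiers() -> ModifierSet:
    return ModifierSet(
        beta_employment=-0.05,
        beta_income=-0.1,
        hr_sickleave=1.5,
        hr_retirement=1.25,
        rr_mortality={
            BMICategory.underweight: 1.0,
            BMICategory.normal: 1.0,
            BMICategory.overweight: 1.2,
            BMICategory.obese: 1.5,
        },
        af_healthcare=0.1,
    )
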