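"""Table/config I/O round-trips and invariant validation."""

import dataclasses
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fiscalbod.model_inputs import (
    BMICategory,
    BMI_BOUNDS,
    CATEGORIES,
    FiscalParams,
    InputValidationError,
    LifeTable,
    ModifierSet,
    RunOptions,
    SchemaError,
    Sex,
    load_config,
    read_life_tables,
    read_stratum_table,
    validate_inputs,
    write_config,
    write_life_tables,
    write_stratum_table,
)

from conftest import make_stratum


def test_bmi_categories_partition_the_bmi_axis():
    bounds = [BMI_BOUNDS[k] for k in CATEGORIES]
    assert bounds[0][0] == 0.0
    assert math.isinf(bounds[-1][1])
    for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
        assert hi1 == lo2  # no gaps, no overlaps
    assert [b[0] for b in bounds[1:]] == [18.5, 25.0, 30.0]


class TestStratumTableIO:
    def test_round_trip_preserves_all_numeric_fields(self, tmp_path):
        strata = [
            make_stratum(),
            make_stratum(age_lo=45, age_hi=49, sex=Sex.male, count=80.0),
            make_stratum(sex=Sex.female, income_ft=123456.789012345),
        ]
        path = tmp_path / "strata.csv"
        write_stratum_table(strata, path)
        back = read_stratum_table(path)
        assert len(back) == 3
        by_key = {s.key: s for s in back}
        for s in strata:
            r = by_key[s.key]
            assert r.count == s.count
            assert r.income_ft == s.income_ft
            for k in CATEGORIES:
                assert r.bmi_proportions[k] == s.bmi_proportions[k]

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age_lo,age_hi,sex\n18,19,male\n")
        with pytest.raises(SchemaError, match="count"):
            read_stratum_table(path)

    def test_broken_simplex_names_the_row(self, tmp_path):
        s = make_stratum()
        write_stratum_table([s], tmp_path / "strata.csv")
        text = (tmp_path / "strata.csv").read_text().replace("0.7", "0.6")
        (tmp_path / "broken.csv").write_text(text)
        with pytest.raises(InputValidationError, match="row 0"):
            read_stratum_table(tmp_path / "broken.csv")

    def test_overlapping_bands_rejected(self, tmp_path):
        strata = [make_stratum(), make_stratum(age_lo=42, age_hi=46)]
        write_stratum_table(strata, tmp_path / "strata.csv")
        with pytest.raises(InputValidationError, match="overlap"):
            read_stratum_table(tmp_path / "strata.csv")

    @given(
        count=st.floats(0, 1e8, allow_nan=False),
        income=st.floats(0, 1e7, allow_nan=False),
        p_obese=st.floats(0.0, 0.3),
    )
    def test_round_trip_is_exact_for_arbitrary_floats(
        self, tmp_path_factory, count, income, p_obese
    ):
        tmp = tmp_path_factory.mktemp("rt")
        props = {
            BMICategory.underweight: 0.05,
            BMICategory.normal: 1.0 - 0.05 - 0.2 - p_obese,
            BMICategory.overweight: 0.2,
            BMICategory.obese: p_obese,
        }
        s = make_stratum(count=count, income_ft=income, bmi_proportions=props)
        write_stratum_table([s], tmp / "s.csv")
        (r,) = read_stratum_table(tmp / "s.csv")
        assert r.count == count and r.income_ft == income
        assert r.bmi_proportions[BMICategory.obese] == p_obese


class TestLifeTables:
    def test_round_trip(self, tmp_path):
        qx = {a: min(1.0, 1e-4 * math.exp(0.09 * a)) for a in range(0, 101)}
        qx[100] = 1.0
        lt = LifeTable(sex=Sex.female, qx=qx, terminal_age=100)
        write_life_tables({Sex.female: lt}, tmp_path / "lt.csv")
        back = read_life_tables(tmp_path / "lt.csv")
        assert back[Sex.female].terminal_age == 100
        assert back[Sex.female].qx[57] == qx[57]

    def test_terminal_qx_must_be_one(self):
        qx = {a: 0.01 for a in range(0, 11)}
        with pytest.raises(InputValidationError, match="terminal"):
            LifeTable(sex=Sex.male, qx=qx, terminal_age=10)

    def test_band_qx_is_unweighted_mean(self):
        qx = {a: a / 100.0 for a in range(0, 10)}
        qx[10] = 1.0
        lt = LifeTable(sex=Sex.male, qx=qx, terminal_age=10)
        assert lt.band_qx(2, 4) == pytest.approx((0.02 + 0.03 + 0.04) / 3)


class TestConfig:
    def test_round_trip_carries_values(self, tmp_path):
        fiscal = FiscalParams(tax_wedge=0.327, vat_rate=0.10)
        mods = ModifierSet(beta_employment={Sex.male: -0.01, Sex.female: -0.03})
        path = tmp_path / "config.ini"
        write_config(fiscal, mods, RunOptions(), path)
        f2, m2, opts = load_config(path)
        assert f2.tax_wedge == 0.327
        assert f2.vat_rate == 0.10
        assert m2.for_sex(Sex.female).beta_employment == -0.03
        assert opts.age_range == (18, 70)

    def test_omitted_sickpay_defaults_to_two_thirds(self, tmp_path):
        path = tmp_path / "config.ini"
        path.write_text("[fiscal]\nvat_rate = 0.10\n")
        fiscal, _, _ = load_config(path)
        assert fiscal.sickpay_fraction == pytest.approx(2 / 3)

    def test_out_of_range_vat_rejected(self, tmp_path):
        path = tmp_path / "config.ini"
        path.write_text("[fiscal]\nvat_rate = 1.5\n")
        with pytest.raises(InputValidationError, match="vat_rate"):
            load_config(path)

    def test_unknown_key_warns_but_loads(self, tmp_path, caplog):
        path = tmp_path / "config.ini"
        path.write_text("[fiscal]\nvat_rate = 0.08\nmystery_knob = 3\n")
        with caplog.at_level("WARNING", logger="fiscalbod"):
            fiscal, _, _ = load_config(path)
        assert fiscal.vat_rate == 0.08
        assert any("mystery_knob" in r.message for r in caplog.records)


class TestValidateInputs:
    def test_valid_fixture_gives_empty_report(self, fixture_set):
        strata, mods, fiscal, lts = fixture_set
        report = validate_inputs(strata, mods, fiscal, lts)
        assert report.ok
        assert report.issues == ()

    def test_nonunit_reference_rr_is_flagged(self):
        mods = ModifierSet(
            rr_mortality={k: (1.2 if k == BMICategory.normal else 1.0) for k in CATEGORIES}
        )
        report = validate_inputs([make_stratum()], mods, FiscalParams())
        assert not report.ok
        (issue,) = report.issues
        assert "normal" in issue.location and "reference" in issue.message

    def test_employment_probabilities_exceeding_one_name_the_stratum(self):
        s = make_stratum(emp_ft=0.9, emp_pt=0.15)
        report = validate_inputs([s], ModifierSet(), FiscalParams())
        assert not report.ok
        (issue,) = report.issues
        assert "40-44" in issue.location
        assert "emp_ft + emp_pt" in issue.message

    def test_validation_is_pure_and_idempotent(self):
        s = make_stratum(emp_ft=0.9, emp_pt=0.15)
        frozen = dataclasses.replace(s)
        r1 = validate_inputs([s], ModifierSet(), FiscalParams())
        r2 = validate_inputs([s], ModifierSet(), FiscalParams())
        assert r1 == r2
        assert s == frozen
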