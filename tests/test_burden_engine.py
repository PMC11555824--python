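"""Counterfactual cohorts, the burden decomposition and the projection."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fiscalbod.burden_engine import (
    annual_fiscal_effect,
    build_control_cohort,
    build_intervention_cohort,
    decade_growth_pct,
    evaluate_burden,
    fiscal_burden,
    project,
    reassign_fraction,
    reduction_curve,
)
from fiscalbod.model_inputs import (
    BMICategory,
    CATEGORIES,
    FiscalFlows,
    FiscalParams,
    ModifierSet,
    OAO_JAPAN,
    OAO_WHO,
    RunOptions,
    Sex,
)
from fiscalbod.synthetic_data import GeneratorSpec, generate_parameter_set

import ledger
from conftest import make_stratum

U, N, O, B = CATEGORIES


def toy_strata():
    return [
        make_stratum(
            count=ledger.STRATUM_A["count"],
            bmi_proportions={
                U: ledger.STRATUM_A["props"]["under"],
                N: ledger.STRATUM_A["props"]["normal"],
                O: ledger.STRATUM_A["props"]["over"],
                B: ledger.STRATUM_A["props"]["obese"],
            },
            emp_ft=ledger.STRATUM_A["emp_ft"],
            emp_pt=ledger.STRATUM_A["emp_pt"],
            income_ft=ledger.STRATUM_A["y_ft"],
            income_pt=ledger.STRATUM_A["y_pt"],
            sickleave_rate=ledger.STRATUM_A["sick"],
            retirement_rate=ledger.STRATUM_A["ret"],
            mepc=ledger.STRATUM_A["mepc"],
            mortality_rate=ledger.STRATUM_A["mort"],
        ),
        make_stratum(
            age_lo=60,
            age_hi=64,
            sex=Sex.female,
            count=ledger.STRATUM_B["count"],
            bmi_proportions={
                U: ledger.STRATUM_B["props"]["under"],
                N: ledger.STRATUM_B["props"]["normal"],
                O: ledger.STRATUM_B["props"]["over"],
                B: ledger.STRATUM_B["props"]["obese"],
            },
            emp_ft=ledger.STRATUM_B["emp_ft"],
            emp_pt=ledger.STRATUM_B["emp_pt"],
            income_ft=ledger.STRATUM_B["y_ft"],
            income_pt=ledger.STRATUM_B["y_pt"],
            sickleave_rate=ledger.STRATUM_B["sick"],
            retirement_rate=ledger.STRATUM_B["ret"],
            mepc=ledger.STRATUM_B["mepc"],
            mortality_rate=ledger.STRATUM_B["mort"],
        ),
    ]


class TestCohortConstruction:
    def test_reassignment_moves_oao_mass_to_normal(self):
        control = build_control_cohort([make_stratum()])
        interv = build_intervention_cohort(control)
        props = interv.strata[0].bmi_proportions
        assert props[U] == pytest.approx(0.1)
        assert props[N] == pytest.approx(0.9)
        assert props[O] == 0.0 and props[B] == 0.0

    def test_population_without_oao_is_unchanged(self):
        s = make_stratum(bmi_proportions={U: 0.1, N: 0.9, O: 0.0, B: 0.0})
        control = build_control_cohort([s])
        interv = build_intervention_cohort(control)
        assert interv.strata[0].bmi_proportions == s.bmi_proportions

    def test_obese_only_definition_reassigns_obese_alone(self):
        control = build_control_cohort([make_stratum()])
        interv = build_intervention_cohort(control, OAO_WHO)
        props = interv.strata[0].bmi_proportions
        assert props[N] == pytest.approx(0.75)
        assert props[O] == pytest.approx(0.15)
        assert props[B] == 0.0

    @given(f=st.floats(0.0, 1.0))
    def test_mass_conservation_under_any_reassignment(self, f):
        control = build_control_cohort(toy_strata())
        reduced = reassign_fraction(control, OAO_JAPAN, f)
        assert reduced.total_count == control.total_count
        for s in reduced.strata:
            assert sum(s.bmi_proportions.values()) == pytest.approx(1.0, rel=1e-12)

    def test_sex_filter_zeroes_counts_but_keeps_shapes(self):
        control = build_control_cohort(
            toy_strata(), RunOptions(sex_filter=Sex.female)
        )
        assert len(control.strata) == 2
        male = [s for s in control.strata if s.sex == Sex.male]
        assert male[0].count == 0.0


class TestAnnualFiscalEffectOracle:
    """The engine must match a hand-written spreadsheet-style ledger."""

    def _results(self, toy_modifiers, toy_fiscal):
        strata = toy_strata()
        options = RunOptions()
        control = build_control_cohort(strata, options)
        interv = build_intervention_cohort(control)
        cf = annual_fiscal_effect(control, toy_modifiers, toy_fiscal, options)
        vf = annual_fiscal_effect(interv, toy_modifiers, toy_fiscal, options)
        return cf, vf

    def test_control_flows_match_hand_ledger(self, toy_modifiers, toy_fiscal):
        (dt, it, tr, hc), _, _ = ledger.annual_ledger()
        cf, _ = self._results(toy_modifiers, toy_fiscal)
        assert cf.direct_tax == pytest.approx(dt, rel=1e-9)
        assert cf.indirect_tax == pytest.approx(it, rel=1e-9)
        assert cf.transfers == pytest.approx(tr, rel=1e-9)
        assert cf.healthcare == pytest.approx(hc, rel=1e-9)

    def test_intervention_flows_match_hand_ledger(self, toy_modifiers, toy_fiscal):
        _, (dt, it, tr, hc), _ = ledger.annual_ledger()
        _, vf = self._results(toy_modifiers, toy_fiscal)
        assert vf.direct_tax == pytest.approx(dt, rel=1e-9)
        assert vf.indirect_tax == pytest.approx(it, rel=1e-9)
        assert vf.transfers == pytest.approx(tr, rel=1e-9)
        assert vf.healthcare == pytest.approx(hc, rel=1e-9)

    def test_burden_matches_hand_ledger(self, toy_modifiers, toy_fiscal):
        _, _, (dt_loss, it_loss, tr_x, hc_x, total) = ledger.annual_ledger()
        cf, vf = self._results(toy_modifiers, toy_fiscal)
        result = fiscal_burden(cf, vf)
        assert result.direct_tax_loss == pytest.approx(dt_loss, rel=1e-9)
        assert result.indirect_tax_loss == pytest.approx(it_loss, rel=1e-9)
        assert result.transfer_excess == pytest.approx(tr_x, rel=1e-9)
        assert result.healthcare_excess == pytest.approx(hc_x, rel=1e-9)
        assert result.total == pytest.approx(total, rel=1e-9)


class TestBurdenIdentities:
    def test_identical_flows_give_zero_burden(self):
        f = FiscalFlows.from_components(10.0, 2.0, 1.0, 3.0)
        result = fiscal_burden(f, f)
        assert result.total == 0.0

    def test_total_is_the_component_sum_and_the_net_difference(
        self, toy_modifiers, toy_fiscal
    ):
        strata = toy_strata()
        control = build_control_cohort(strata)
        interv = build_intervention_cohort(control)
        cf = annual_fiscal_effect(control, toy_modifiers, toy_fiscal)
        vf = annual_fiscal_effect(interv, toy_modifiers, toy_fiscal)
        r = fiscal_burden(cf, vf)
        assert r.total == pytest.approx(
            r.direct_tax_loss + r.indirect_tax_loss + r.transfer_excess + r.healthcare_excess,
            rel=1e-12,
        )
        assert r.total == pytest.approx(vf.net - cf.net, rel=1e-9)

    def test_zero_population_means_zero_flows(self, toy_modifiers, toy_fiscal):
        strata = [make_stratum(count=0.0)]
        control = build_control_cohort(strata)
        flows = annual_fiscal_effect(control, toy_modifiers, toy_fiscal)
        assert flows.net == 0.0 and flows.healthcare == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_null_modifiers_give_zero_burden_on_random_populations(self, seed):
        """beta=0, HR=1, AF=0, RR=1 implies the counterfactual changes nothing."""
        strata, _, fiscal, _ = generate_parameter_set(GeneratorSpec(seed=seed))
        result = evaluate_burden(strata, ModifierSet.null(), fiscal)
        flows = annual_fiscal_effect(
            build_control_cohort(strata), ModifierSet.null(), fiscal
        )
        scale = abs(flows.direct_tax) + abs(flows.healthcare)
        assert abs(result.total) / scale < 1e-9


class TestReductionCurve:
    def test_endpoints_and_monotonicity(self, toy_modifiers, toy_fiscal):
        strata = toy_strata()
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        curve = reduction_curve(strata, toy_modifiers, toy_fiscal, fractions)
        burden = evaluate_burden(strata, toy_modifiers, toy_fiscal)
        assert curve[0.0] == 0.0
        assert curve[1.0] == pytest.approx(burden.total, rel=1e-9)
        gains = [curve[f] for f in fractions]
        assert all(b > a for a, b in zip(gains, gains[1:]))


class TestProjection:
    def test_single_step_scales_by_the_wage_factor_without_growth(
        self, toy_modifiers, toy_fiscal
    ):
        """With zero prevalence growth every monetary input grows with
        wages, so the year-1 burden is the base burden times (1 + g)."""
        import dataclasses

        fiscal = dataclasses.replace(
            toy_fiscal, prevalence_growth={Sex.male: 0.0, Sex.female: 0.0}
        )
        strata = toy_strata()
        proj = project(strata, toy_modifiers, fiscal, horizon=1)
        base = proj.per_year[0].total
        assert proj.per_year[1].total == pytest.approx(
            base * (1 + fiscal.wage_growth), rel=1e-9
        )

    def test_zero_discount_npv_equals_plain_sum(self, toy_modifiers, toy_fiscal):
        import dataclasses

        fiscal = dataclasses.replace(toy_fiscal, discount_rate=0.0)
        proj = project(toy_strata(), toy_modifiers, fiscal, horizon=3)
        assert proj.npv_total == pytest.approx(
            sum(r.total for r in proj.per_year.values()), rel=1e-12
        )

    def test_npv_is_the_discounted_sum(self, toy_modifiers, toy_fiscal):
        proj = project(toy_strata(), toy_modifiers, toy_fiscal, horizon=4)
        expected = sum(
            r.total / (1 + toy_fiscal.discount_rate) ** t
            for t, r in proj.per_year.items()
        )
        assert proj.npv_total == pytest.approx(expected, rel=1e-12)

    def test_growing_prevalence_grows_the_discounted_burden(
        self, toy_modifiers, toy_fiscal
    ):
        """With wage growth equal to the discount rate, any rise in the
        discounted series is attributable to prevalence growth alone."""
        proj = project(toy_strata(), toy_modifiers, toy_fiscal, horizon=5)
        discounted = [
            proj.per_year[t].total / (1 + toy_fiscal.discount_rate) ** t
            for t in sorted(proj.per_year)
        ]
        assert all(b > a for a, b in zip(discounted, discounted[1:]))

    def test_decade_growth_is_computed_from_the_series(
        self, toy_modifiers, toy_fiscal
    ):
        proj = project(toy_strata(), toy_modifiers, toy_fiscal, horizon=10)
        pct = decade_growth_pct(proj, toy_fiscal)
        base = proj.per_year[0].total
        end = proj.per_year[10].total / (1 + toy_fiscal.discount_rate) ** 10
        assert pct == pytest.approx(100 * (end - base) / base, rel=1e-12)
        assert pct > 0
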