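"""Counterfactual cohort construction and the fiscal burden computation.

The observed population forms the *control* cohort; the *intervention*
cohort reassigns every OAO individual to the normal-weight category
(counts conserved). Annual government flows — direct tax, indirect tax,
pension transfers, healthcare — are computed for both cohorts and the
burden of OAO is the control-minus-intervention difference, reported
with burden-positive signs. A prevalence-reduction curve and a
multi-year projection (growing OAO prevalence, wage growth,
discounting) are layered on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .health_and_mortality import (
    MortalityInputs,
    adjust_mepc,
    derive_case_distribution,
    rockhill_paf,
)
from .labor_and_tax import GROUP_OAO, GROUP_REFERENCE, stratum_group_outcome
from .model_inputs import (
    BMICategory,
    BurdenResult,
    CATEGORIES,
    FiscalFlows,
    FiscalParams,
    ModifierSet,
    OAO_JAPAN,
    PopulationStratum,
    RunOptions,
    Sex,
)

logger = logging.getLogger("fiscalbod")

__all__ = [
    "Cohort",
    "ProjectionResult",
    "build_control_cohort",
    "build_intervention_cohort",
    "reassign_fraction",
    "stratum_paf",
    "annual_fiscal_effect",
    "fiscal_burden",
    "evaluate_burden",
    "reduction_curve",
    "project",
    "decade_growth_pct",
]


@dataclass(frozen=True)
class Cohort:
    """A population with a role in the counterfactual comparison.

    ``mepc_reference`` carries the *source* population's BMI prevalence
    per stratum: the per-category medical-cost profile is always derived
    from the observed prevalence, so that reassigning OAO mass to normal
    weight removes the attributable cost rather than re-spreading it.
    """

    role: str
    strata: tuple[PopulationStratum, ...]
    mepc_reference: tuple[Mapping[BMICategory, float], ...]

    @property
    def total_count(self) -> float:
        return sum(s.count for s in self.strata)


def _band_in_range(s: PopulationStratum, age_range: tuple[int, int]) -> bool:
    lo, hi = age_range
    return s.age_hi >= lo and s.age_lo <= hi


def build_control_cohort(
    strata: Sequence[PopulationStratum], options: RunOptions | None = None
) -> Cohort:
    """Select the in-scope strata (age range / sex filter) as the control cohort.

    A sex filter zeroes the excluded sex's counts rather than dropping
    strata, keeping output shapes constant across scenarios.
    """
    options = options or RunOptions()
    selected = [s for s in strata if _band_in_range(s, options.age_range)]
    if options.sex_filter is not None:
        selected = [
            s if s.sex == options.sex_filter else replace(s, count=0.0)
            for s in selected
        ]
    return Cohort(
        role="control",
        strata=tuple(selected),
        mepc_reference=tuple(dict(s.bmi_proportions) for s in selected),
    )


def _reassign(
    props: Mapping[BMICategory, float],
    oao_set: frozenset[BMICategory],
    fraction: float,
) -> dict[BMICategory, float]:
    out = dict(props)
    moved = 0.0
    for k in oao_set:
        delta = out[k] * fraction
        out[k] -= delta
        moved += delta
    out[BMICategory.normal] += moved
    return out


def build_intervention_cohort(
    control: Cohort, oao_set: frozenset[BMICategory] = OAO_JAPAN
) -> Cohort:
    """Counterfactual cohort: all OAO mass reassigned to normal weight.

    Counts are untouched (mass conservation); only the BMI proportions
    change, and they remain a simplex.
    """
    return reassign_fraction(control, oao_set, 1.0)


def reassign_fraction(
    control: Cohort, oao_set: frozenset[BMICategory], fraction: float
) -> Cohort:
    """Reassign ``fraction`` of each OAO category's share to normal weight."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    strata = tuple(
        replace(s, bmi_proportions=_reassign(s.bmi_proportions, oao_set, fraction))
        for s in control.strata
    )
    role = "intervention" if fraction == 1.0 else f"reassigned_{fraction:g}"
    return Cohort(role=role, strata=strata, mepc_reference=control.mepc_reference)


def stratum_paf(
    stratum: PopulationStratum,
    rr: Mapping[BMICategory, float],
) -> float:
    """Rockhill PAF for one stratum from its own prevalence and an RR map."""
    if sum(stratum.bmi_proportions[k] for k in CATEGORIES) <= 0.0:
        return 0.0
    pd_map = derive_case_distribution(stratum.bmi_proportions, rr)
    return rockhill_paf(MortalityInputs(pd=pd_map, rr=rr))


def _stratum_flows(
    stratum: PopulationStratum,
    ref_prev: Mapping[BMICategory, float],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    options: RunOptions,
) -> FiscalFlows:
    mods = modifiers.for_sex(stratum.sex)
    prev = stratum.bmi_proportions
    oao_set = options.oao_set

    # Healthcare: category cost profile anchored on the source prevalence.
    profile = adjust_mepc(stratum.mepc, ref_prev, mods.af_healthcare, oao_set)
    healthcare = sum(
        stratum.count * prev[k] * profile.mepc_by_category[k] for k in CATEGORIES
    )

    # OAO-attributable deaths shave person-years off the OAO group's
    # labor and transfer flows (half a year per death, mid-year rule).
    rr = mods.rr_for_age(stratum.age_lo, options.use_elderly_rr)
    paf = stratum_paf(stratum, rr)
    n_oao = stratum.count * sum(prev[k] for k in oao_set)
    py_loss = 0.0
    if options.mortality_affects_flows and n_oao > 0.0:
        oao_deaths = paf * stratum.count * stratum.mortality_rate
        py_loss = 0.5 * oao_deaths

    dt = it = tr = 0.0
    for k in CATEGORIES:
        n_k = stratum.count * prev[k]
        if n_k <= 0.0:
            continue
        group = GROUP_OAO if k in oao_set else GROUP_REFERENCE
        if group == GROUP_OAO and n_oao > 0.0:
            n_k = n_k * (1.0 - py_loss / n_oao)
        outcome = stratum_group_outcome(
            stratum, group, mods, fiscal, n_k, options.sickleave_scope
        )
        dt += fiscal.tax_wedge * outcome.income_total
        it += fiscal.vat_rate * (
            outcome.disposable_income + outcome.transfer_income
        )
        tr += outcome.transfer_income
    return FiscalFlows.from_components(dt, it, tr, healthcare)


def annual_fiscal_effect(
    cohort: Cohort,
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    options: RunOptions | None = None,
    by_stratum: bool = False,
) -> FiscalFlows | tuple[FiscalFlows, dict[tuple[int, int, Sex], FiscalFlows]]:
    """Total annual government flows for a cohort (one model year).

    Sums tax revenue (direct via the tax wedge, indirect via VAT on
    disposable income and transfers) and government spending (pension
    transfers, healthcare) over every stratum and BMI group.
    """
    options = options or RunOptions()
    total = FiscalFlows.zero()
    detail: dict[tuple[int, int, Sex], FiscalFlows] = {}
    for s, ref_prev in zip(cohort.strata, cohort.mepc_reference):
        flows = _stratum_flows(s, ref_prev, modifiers, fiscal, options)
        total = total + flows
        if by_stratum:
            detail[s.key] = flows
    if by_stratum:
        return total, detail
    return total


def fiscal_burden(
    control_flows: FiscalFlows, intervention_flows: FiscalFlows
) -> BurdenResult:
    """Incremental fiscal effect of OAO, burden components positive.

    Tax components are intervention minus control (revenue the
    government forgoes); spending components are control minus
    intervention (excess outlays). The total equals the difference in
    net fiscal effect between the two cohorts.
    """
    return BurdenResult.from_components(
        direct_tax_loss=intervention_flows.direct_tax - control_flows.direct_tax,
        indirect_tax_loss=intervention_flows.indirect_tax
        - control_flows.indirect_tax,
        transfer_excess=control_flows.transfers - intervention_flows.transfers,
        healthcare_excess=control_flows.healthcare - intervention_flows.healthcare,
    )


def evaluate_burden(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    options: RunOptions | None = None,
    by_stratum: bool = False,
) -> BurdenResult:
    """End-to-end single-year burden: build cohorts, compare flows."""
    options = options or RunOptions()
    control = build_control_cohort(strata, options)
    intervention = build_intervention_cohort(control, options.oao_set)
    if by_stratum:
        cf, cd = annual_fiscal_effect(control, modifiers, fiscal, options, True)
        vf, vd = annual_fiscal_effect(intervention, modifiers, fiscal, options, True)
        detail = {key: fiscal_burden(cd[key], vd[key]) for key in cd}
        base = fiscal_burden(cf, vf)
        return replace(base, by_stratum=detail)
    cf = annual_fiscal_effect(control, modifiers, fiscal, options)
    vf = annual_fiscal_effect(intervention, modifiers, fiscal, options)
    return fiscal_burden(cf, vf)


def reduction_curve(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    fractions: Sequence[float],
    options: RunOptions | None = None,
) -> dict[float, float]:
    """Net fiscal gain from reassigning a fraction of OAO prevalence to normal.

    The gain at fraction f is the net-flow improvement over the control
    cohort; f = 0 gives 0 and f = 1 gives the full burden total.
    """
    options = options or RunOptions()
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0,1]")
    control = build_control_cohort(strata, options)
    base = annual_fiscal_effect(control, modifiers, fiscal, options)
    out: dict[float, float] = {}
    for f in fractions:
        reduced = reassign_fraction(control, options.oao_set, f)
        flows = annual_fiscal_effect(reduced, modifiers, fiscal, options)
        out[float(f)] = flows.net - base.net
    return out


@dataclass(frozen=True)
class ProjectionResult:
    """Multi-year burden series: undiscounted per-year results plus NPV."""

    per_year: Mapping[int, BurdenResult]
    npv_total: float
    base_year: int = 0


def _grown_strata(
    strata: Sequence[PopulationStratum],
    fiscal: FiscalParams,
    options: RunOptions,
    t: int,
    projections: pd.DataFrame | None = None,
) -> list[PopulationStratum]:
    """Inputs for model year t: OAO prevalence, wages and costs grown.

    The combined OAO (overweight + obese) share grows multiplicatively
    at the sex-specific rate, drawn from the normal-weight share and
    clamped so it never goes negative; the internal overweight:obese
    ratio is preserved. Wages follow wage growth; medical expenditure
    and the pension benefit follow it too unless switched off. Counts
    come from the projections table when given, otherwise held flat.
    """
    wage_f = (1.0 + fiscal.wage_growth) ** t
    mepc_f = wage_f if options.grow_mepc else 1.0
    out = []
    for s in strata:
        growth_f = (1.0 + fiscal.growth_for(s.sex)) ** t
        props = dict(s.bmi_proportions)
        p_oao = sum(props[k] for k in OAO_JAPAN)
        if p_oao > 0.0:
            target = p_oao * growth_f
            delta = target - p_oao
            avail = props[BMICategory.normal]
            if delta > avail:
                logger.warning(
                    "stratum [%d,%d,%s], year %d: OAO growth clamped "
                    "(normal-weight share exhausted)",
                    s.age_lo,
                    s.age_hi,
                    s.sex.value,
                    t,
                )
                delta = avail
                target = p_oao + delta
            scale = target / p_oao
            for k in OAO_JAPAN:
                props[k] *= scale
            props[BMICategory.normal] -= delta
        count = s.count
        if projections is not None:
            match = projections[
                (projections["year"] == t)
                & (projections["sex"] == s.sex.value)
                & (projections["age_lo"] == s.age_lo)
                & (projections["age_hi"] == s.age_hi)
            ]
            if len(match):
                count = float(match["count"].iloc[0])
        out.append(
            replace(
                s,
                count=count,
                bmi_proportions=props,
                income_ft=s.income_ft * wage_f,
                income_pt=s.income_pt * wage_f,
                mepc=s.mepc * mepc_f,
            )
        )
    return out


def project(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    options: RunOptions | None = None,
    horizon: int | None = None,
    projections: pd.DataFrame | None = None,
) -> ProjectionResult:
    """Project the annual burden over a horizon of years.

    Year 0 is the base year (undiscounted); each later year regrows the
    inputs, recomputes the burden, and the NPV discounts the per-year
    totals at the configured rate. The pension benefit is grown
    alongside wages (switchable), so with zero prevalence growth the
    whole burden scales by the wage factor.
    """
    options = options or RunOptions()
    horizon = fiscal.horizon_years if horizon is None else horizon
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    per_year: dict[int, BurdenResult] = {}
    npv = 0.0
    for t in range(horizon + 1):
        strata_t = _grown_strata(strata, fiscal, options, t, projections)
        fiscal_t = (
            replace(
                fiscal,
                pension_benefit=fiscal.pension_benefit
                * (1.0 + fiscal.wage_growth) ** t,
            )
            if options.grow_pension
            else fiscal
        )
        result = evaluate_burden(strata_t, modifiers, fiscal_t, options)
        per_year[t] = result
        npv += result.total / (1.0 + fiscal.discount_rate) ** t
    return ProjectionResult(per_year=per_year, npv_total=npv, base_year=0)


def decade_growth_pct(result: ProjectionResult, fiscal: FiscalParams) -> float:
    """Percentage growth of the burden from the base year to the horizon end.

    The horizon-year total is discounted back to the base year before
    comparison, so the figure isolates epidemiological and demographic
    growth from pure wage inflation (wage growth and the discount rate
    offset when equal).
    """
    years = sorted(result.per_year)
    first, last = years[0], years[-1]
    base = result.per_year[first].total
    end = result.per_year[last].total / (1.0 + fiscal.discount_rate) ** (
        last - first
    )
    if base == 0.0:
        raise ZeroDivisionError("base-year burden is zero")
    return 100.0 * (end - base) / base
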