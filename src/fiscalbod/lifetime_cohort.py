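"""Per-person lifetime present-value comparison: OAO vs non-OAO peer.

Two single-person arms start at the same age and keep their obesity
status for life. Each year the arm accrues tax payments (while working),
pension receipts (once retired) and healthcare costs; annual death
probabilities come from the life table, split between arms so that the
OAO arm carries the relative-risk-scaled hazard while the
population-average hazard still matches the table. The per-person
lifetime fiscal burden is the present-value difference between the
non-OAO and OAO arms.

Retirement schedule: both arms face the stratum's early-retirement
hazard from age 50 (the OAO arm's hazard is scaled by the hazard
ratio) and statutory retirement at 65; this keeps the two arms
identical when every modifier is null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .health_and_mortality import adjust_mepc
from .labor_and_tax import (
    GROUP_OAO,
    GROUP_REFERENCE,
    adjust_employment,
    adjust_income,
    adjust_welfare_rate,
    total_income,
)
from .model_inputs import (
    BMICategory,
    CATEGORIES,
    DomainError,
    FiscalParams,
    LifeTable,
    ModifierSet,
    PopulationStratum,
    ResolvedModifiers,
    RunOptions,
    Sex,
)

__all__ = [
    "STATUTORY_RETIREMENT_AGE",
    "EARLY_RETIREMENT_FROM",
    "LifetimePath",
    "LifetimeResult",
    "lifetime_fiscal_effect",
    "lifetime_age_sweep",
]

STATUTORY_RETIREMENT_AGE = 65
EARLY_RETIREMENT_FROM = 50


@dataclass(frozen=True)
class LifetimePath:
    """Age-resolved trace of one lifetime comparison (single sex)."""

    start_age: int
    sex: Sex
    ages: tuple[int, ...]
    survival_ref: tuple[float, ...]
    survival_oao: tuple[float, ...]
    pv_net_ref: float
    pv_net_oao: float


@dataclass(frozen=True)
class LifetimeResult:
    """Per-person lifetime fiscal burden, decomposed as in the annual model."""

    start_age: int
    tax_loss: float
    transfer_excess: float
    total: float
    paths: tuple[LifetimePath, ...] = ()


def _stratum_for_age(
    by_sex: Mapping[Sex, Sequence[PopulationStratum]], sex: Sex, age: int
) -> PopulationStratum:
    """Band containing ``age``; clamped to the nearest band outside coverage."""
    strata = by_sex[sex]
    for s in strata:
        if s.age_lo <= age <= s.age_hi:
            return s
    return strata[0] if age < strata[0].age_lo else strata[-1]


def _oao_rr_bar(
    prev: Mapping[BMICategory, float],
    rr: Mapping[BMICategory, float],
    oao_set: frozenset[BMICategory],
) -> tuple[float, float]:
    """Combined OAO prevalence and its prevalence-weighted relative risk."""
    p = sum(prev[k] for k in oao_set)
    if p <= 0.0:
        return 0.0, 1.0
    rr_bar = sum(prev[k] * rr.get(k, 1.0) for k in oao_set) / p
    return p, rr_bar


def _group_mepc(
    stratum: PopulationStratum,
    mods: ResolvedModifiers,
    oao_set: frozenset[BMICategory],
    group: str,
) -> float:
    """Per-person medical expenditure for one arm at this stratum's age."""
    profile = adjust_mepc(
        stratum.mepc, stratum.bmi_proportions, mods.af_healthcare, oao_set
    )
    cats = [k for k in CATEGORIES if (k in oao_set) == (group == GROUP_OAO)]
    weight = sum(stratum.bmi_proportions[k] for k in cats)
    if weight <= 0.0:
        return profile.mepc_by_category[
            BMICategory.obese if group == GROUP_OAO else BMICategory.normal
        ]
    return (
        sum(stratum.bmi_proportions[k] * profile.mepc_by_category[k] for k in cats)
        / weight
    )


def _arm_pv(
    sex: Sex,
    group: str,
    start_age: int,
    by_sex: Mapping[Sex, Sequence[PopulationStratum]],
    mods: ResolvedModifiers,
    fiscal: FiscalParams,
    life_table: LifeTable,
    options: RunOptions,
) -> tuple[float, float, float, float, tuple[float, ...]]:
    """Discounted per-person (direct tax, indirect tax, pension, healthcare).

    Returns the four component present values and the survival curve
    (probability of being alive at the start of each model year).
    """
    survival = 1.0
    retired = 1.0 if start_age >= STATUTORY_RETIREMENT_AGE else 0.0
    pv_dt = pv_it = pv_tr = pv_hc = 0.0
    surv_path: list[float] = []
    for age in range(start_age, life_table.terminal_age + 1):
        if age >= STATUTORY_RETIREMENT_AGE:
            retired = 1.0
        surv_path.append(survival)
        t = age - start_age
        wage_f = (1.0 + fiscal.wage_growth) ** t
        disc_f = (1.0 + fiscal.discount_rate) ** (-t)
        s = _stratum_for_age(by_sex, sex, age)

        # Labor and transfer flows for one person with stock retirement
        # probability `retired`.
        if group == GROUP_OAO:
            p_sl = adjust_welfare_rate(s.sickleave_rate, mods.hr_sickleave)
        else:
            p_sl = s.sickleave_rate
        p_ft = adjust_employment(s.emp_ft, mods.beta_employment, group)
        p_pt = adjust_employment(s.emp_pt, mods.beta_employment, group)
        y_ft = adjust_income(s.income_ft, mods.beta_income, group) * wage_f
        y_pt = adjust_income(s.income_pt, mods.beta_income, group) * wage_f
        pension_f = wage_f if options.grow_pension else 1.0
        fiscal_t = fiscal if pension_f == 1.0 else _scaled_pension(fiscal, pension_f)
        outcome = total_income(
            1.0, p_ft, p_pt, p_sl, retired, y_ft, y_pt, fiscal_t,
            options.sickleave_scope,
        )
        mepc_f = wage_f if options.grow_mepc else 1.0
        hc = _group_mepc(s, mods, options.oao_set, group) * mepc_f

        w = survival * disc_f
        pv_dt += w * fiscal.tax_wedge * outcome.income_total
        pv_it += w * fiscal.vat_rate * (
            outcome.disposable_income + outcome.transfer_income
        )
        pv_tr += w * outcome.transfer_income
        pv_hc += w * hc

        # Mortality split between arms, anchored on the life table.
        qx = life_table.annual_qx(age)
        rr_map = mods.rr_for_age(age, options.use_elderly_rr)
        p_oao, rr_bar = _oao_rr_bar(s.bmi_proportions, rr_map, options.oao_set)
        qx_ref = qx / (1.0 - p_oao + p_oao * rr_bar)
        qx_arm = min(1.0, rr_bar * qx_ref) if group == GROUP_OAO else qx_ref
        survival *= 1.0 - qx_arm

        # Early-retirement hazard next year (both arms, OAO scaled by HR).
        if EARLY_RETIREMENT_FROM <= age < STATUTORY_RETIREMENT_AGE:
            h = s.retirement_rate
            if group == GROUP_OAO:
                h = adjust_welfare_rate(h, mods.hr_retirement)
            retired += (1.0 - retired) * h
    return pv_dt, pv_it, pv_tr, pv_hc, tuple(surv_path)


def _scaled_pension(fiscal: FiscalParams, factor: float) -> FiscalParams:
    from dataclasses import replace

    return replace(fiscal, pension_benefit=fiscal.pension_benefit * factor)


def lifetime_fiscal_effect(
    start_age: int,
    sex_mix: Mapping[Sex, float],
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    life_tables: Mapping[Sex, LifeTable],
    options: RunOptions | None = None,
    keep_paths: bool = False,
) -> LifetimeResult:
    """Per-person lifetime fiscal burden of OAO starting at ``start_age``.

    ``sex_mix`` weights the male/female paths (e.g. ``{male: .5,
    female: .5}``); the burden is pv(non-OAO arm) - pv(OAO arm), split
    into a tax-revenue-loss component and an excess transfer+healthcare
    component.
    """
    options = options or RunOptions()
    by_sex: dict[Sex, list[PopulationStratum]] = {s: [] for s in Sex}
    for s in strata:
        by_sex[s.sex].append(s)
    for sex in Sex:
        by_sex[sex].sort(key=lambda s: s.age_lo)

    total_mix = sum(sex_mix.values())
    if abs(total_mix - 1.0) > 1e-9:
        raise DomainError(f"sex mix sums to {total_mix}, expected 1")

    tax_ref = tax_oao = spend_ref = spend_oao = 0.0
    net_ref = net_oao = 0.0
    paths: list[LifetimePath] = []
    for sex, weight in sex_mix.items():
        if weight == 0.0:
            continue
        lt = life_tables[sex]
        if start_age > lt.terminal_age:
            raise DomainError(
                f"start age {start_age} beyond terminal age {lt.terminal_age}"
            )
        if not by_sex[sex]:
            raise DomainError(f"no strata for sex {sex.value}")
        mods = modifiers.for_sex(sex)
        dt_r, it_r, tr_r, hc_r, surv_r = _arm_pv(
            sex, GROUP_REFERENCE, start_age, by_sex, mods, fiscal, lt, options
        )
        dt_o, it_o, tr_o, hc_o, surv_o = _arm_pv(
            sex, GROUP_OAO, start_age, by_sex, mods, fiscal, lt, options
        )
        tax_ref += weight * (dt_r + it_r)
        tax_oao += weight * (dt_o + it_o)
        spend_ref += weight * (tr_r + hc_r)
        spend_oao += weight * (tr_o + hc_o)
        net_ref += weight * (dt_r + it_r - tr_r - hc_r)
        net_oao += weight * (dt_o + it_o - tr_o - hc_o)
        if keep_paths:
            ages = tuple(range(start_age, lt.terminal_age + 1))
            paths.append(
                LifetimePath(
                    start_age=start_age,
                    sex=sex,
                    ages=ages,
                    survival_ref=surv_r,
                    survival_oao=surv_o,
                    pv_net_ref=dt_r + it_r - tr_r - hc_r,
                    pv_net_oao=dt_o + it_o - tr_o - hc_o,
                )
            )

    tax_loss = tax_ref - tax_oao
    transfer_excess = spend_oao - spend_ref
    return LifetimeResult(
        start_age=start_age,
        tax_loss=tax_loss,
        transfer_excess=transfer_excess,
        total=net_ref - net_oao,
        paths=tuple(paths),
    )


def lifetime_age_sweep(
    ages: Sequence[int],
    sex_mix: Mapping[Sex, float],
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    life_tables: Mapping[Sex, LifeTable],
    options: RunOptions | None = None,
) -> dict[int, LifetimeResult]:
    """One-way sweep of the lifetime model over starting ages."""
    return {
        age: lifetime_fiscal_effect(
            age, sex_mix, strata, modifiers, fiscal, life_tables, options
        )
        for age in ages
    }
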