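"""Labor-market adjustment and tax-flow arithmetic.

Implements the employment/income/welfare adjustments for the OAO group
and the aggregation of stratum income into direct tax (tax wedge) and
indirect tax (VAT on disposable income plus government transfers).

Conventions
-----------
* The employment marginal effect is additive on the probability scale
  and applied identically to full-time and part-time employment.
* The income marginal effect is relative (a wage-regression effect).
* Hazard ratios multiply baseline sick-leave / retirement rates.
* Retired persons are removed from the employment-eligible pool before
  employment probabilities apply, so nobody is simultaneously counted
  as retired and employed.
* Sick leave applies to full-time workers only in the base case; the
  ``ft_and_pt`` scope extends the sick-leave split to part-time workers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_inputs import (
    DomainError,
    FiscalParams,
    PopulationStratum,
    ResolvedModifiers,
)

__all__ = [
    "GROUP_REFERENCE",
    "GROUP_OAO",
    "LaborOutcome",
    "adjust_employment",
    "adjust_welfare_rate",
    "adjust_income",
    "total_income",
    "direct_tax",
    "indirect_tax",
    "stratum_group_outcome",
]

GROUP_REFERENCE = "reference"
GROUP_OAO = "oao"


@dataclass(frozen=True)
class LaborOutcome:
    """Labor and income state of one (stratum, BMI-group) cell.

    Probabilities are per person; ``income_total``, ``disposable_income``
    and ``transfer_income`` are aggregates over the cell (JPY/year).
    """

    p_ft: float
    p_pt: float
    p_sickleave: float
    p_retired: float
    income_total: float
    disposable_income: float
    transfer_income: float


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def adjust_employment(p_gp: float, beta: float, group: str) -> float:
    """OAO-adjusted employment probability.

    The reference group keeps the general-population probability; the OAO
    group shifts it by the additive marginal effect ``beta``, clamped to
    [0, 1].
    """
    if not 0.0 <= p_gp <= 1.0:
        raise DomainError(f"employment probability {p_gp} outside [0,1]")
    if group == GROUP_REFERENCE:
        return p_gp
    return _clamp01(p_gp + beta)


def adjust_welfare_rate(rate_gp: float, hr: float) -> float:
    """Sick-leave or retirement rate scaled by a hazard ratio, clamped to [0,1]."""
    if not 0.0 <= rate_gp <= 1.0:
        raise DomainError(f"welfare rate {rate_gp} outside [0,1]")
    if hr < 0:
        raise DomainError(f"hazard ratio must be >= 0, got {hr}")
    return _clamp01(rate_gp * hr)


def adjust_income(y_gp: float, beta_income: float, group: str) -> float:
    """OAO-adjusted annual income via the relative marginal effect."""
    if y_gp < 0:
        raise DomainError(f"income must be >= 0, got {y_gp}")
    if group == GROUP_REFERENCE:
        return y_gp
    return max(y_gp * (1.0 + beta_income), 0.0)


def total_income(
    n: float,
    p_ft: float,
    p_pt: float,
    p_sickleave: float,
    p_retired: float,
    y_ft: float,
    y_pt: float,
    fiscal: FiscalParams,
    sickleave_scope: str = "ft_only",
) -> LaborOutcome:
    """Aggregate labor income and transfer income for a cell of ``n`` persons.

    Retired persons are removed from the employment-eligible pool first.
    Full-time workers split into active (full salary) and on sick leave
    (``sickpay_fraction`` of salary); under the ``ft_and_pt`` scope the
    same split applies to part-time workers, otherwise part-timers earn
    their full salary. Transfer income is the pension paid to retirees.
    """
    if sickleave_scope not in {"ft_only", "ft_and_pt"}:
        raise DomainError(f"unknown sickleave scope {sickleave_scope!r}")
    eligible = 1.0 - p_retired
    eff_ft = p_ft * eligible
    eff_pt = p_pt * eligible
    spf = fiscal.sickpay_fraction
    ft_part = eff_ft * ((1.0 - p_sickleave) + p_sickleave * spf) * y_ft
    if sickleave_scope == "ft_and_pt":
        pt_part = eff_pt * ((1.0 - p_sickleave) + p_sickleave * spf) * y_pt
    else:
        pt_part = eff_pt * y_pt
    income = n * (ft_part + pt_part)
    transfer = n * p_retired * fiscal.pension_benefit
    return LaborOutcome(
        p_ft=p_ft,
        p_pt=p_pt,
        p_sickleave=p_sickleave,
        p_retired=p_retired,
        income_total=income,
        disposable_income=income * (1.0 - fiscal.tax_wedge),
        transfer_income=transfer,
    )


def direct_tax(income_total: float, fiscal: FiscalParams) -> float:
    """Direct tax revenue: the tax wedge applied to total labor income."""
    if income_total < 0:
        raise DomainError(f"income must be >= 0, got {income_total}")
    return fiscal.tax_wedge * income_total


def indirect_tax(
    disposable_income: float, transfer_income: float, fiscal: FiscalParams
) -> float:
    """Indirect (consumption) tax: VAT on disposable income plus transfers."""
    if disposable_income < 0 or transfer_income < 0:
        raise DomainError("disposable and transfer income must be >= 0")
    return fiscal.vat_rate * (disposable_income + transfer_income)


def stratum_group_outcome(
    stratum: PopulationStratum,
    group: str,
    modifiers: ResolvedModifiers,
    fiscal: FiscalParams,
    n: float,
    sickleave_scope: str = "ft_only",
    retirement_hr_applies: bool | None = None,
) -> LaborOutcome:
    """Full per-cell pipeline: adjust rates/incomes, then aggregate.

    ``n`` is the cell's person count (a BMI category's share of the
    stratum, possibly mortality-reduced). The retirement hazard ratio is
    an *early*-retirement effect, so by default it applies only to bands
    below the statutory retirement age of 65.
    """
    if retirement_hr_applies is None:
        retirement_hr_applies = stratum.age_lo < 65
    if group == GROUP_OAO:
        p_ret = (
            adjust_welfare_rate(stratum.retirement_rate, modifiers.hr_retirement)
            if retirement_hr_applies
            else stratum.retirement_rate
        )
        p_sl = adjust_welfare_rate(stratum.sickleave_rate, modifiers.hr_sickleave)
    else:
        p_ret = stratum.retirement_rate
        p_sl = stratum.sickleave_rate
    p_ft = adjust_employment(stratum.emp_ft, modifiers.beta_employment, group)
    p_pt = adjust_employment(stratum.emp_pt, modifiers.beta_employment, group)
    y_ft = adjust_income(stratum.income_ft, modifiers.beta_income, group)
    y_pt = adjust_income(stratum.income_pt, modifiers.beta_income, group)
    return total_income(
        n, p_ft, p_pt, p_sl, p_ret, y_ft, y_pt, fiscal, sickleave_scope
    )
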