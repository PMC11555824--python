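"""One-way sensitivity analysis (tornado) and the scenario battery.

``run_owsa`` perturbs one parameter at a time between a low and a high
value and records the resulting annual burden total; rows sorted by bar
width give the tornado diagram. ``run_scenarios`` reruns the whole
pipeline under structural overrides (age range, obesity definition,
alternate elderly mortality, sick-leave scope, single-sex populations)
and reports the tax-loss / transfer-spending / net decomposition per
scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import pandas as pd

from .burden_engine import evaluate_burden
from .model_inputs import (
    BMICategory,
    FiscalParams,
    ModifierSet,
    OAO_WHO,
    PopulationStratum,
    RunOptions,
    Sex,
)

__all__ = [
    "OwsaSpec",
    "ScenarioSpec",
    "default_owsa_specs",
    "run_owsa",
    "table2_battery",
    "run_scenarios",
]


@dataclass(frozen=True)
class OwsaSpec:
    """One tornado bar: a dotted parameter path and its low/high values.

    Paths address ``fiscal.<field>``, ``modifiers.<field>`` or
    ``modifiers.rr_mortality.<category>``.
    """

    parameter: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(
                f"{self.parameter}: low {self.low} exceeds high {self.high}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named structural variant of the base case."""

    name: str
    overrides: Mapping[str, Any] = dataclasses.field(default_factory=dict)


_SCALAR_MOD_FIELDS = {
    "beta_employment",
    "beta_income",
    "hr_sickleave",
    "hr_retirement",
    "af_healthcare",
}


def _set_param(
    modifiers: ModifierSet, fiscal: FiscalParams, path: str, value: float
) -> tuple[ModifierSet, FiscalParams]:
    parts = path.split(".")
    if parts[0] == "fiscal" and len(parts) == 2:
        if not hasattr(fiscal, parts[1]):
            raise KeyError(f"unknown parameter path {path!r}")
        return modifiers, dataclasses.replace(fiscal, **{parts[1]: value})
    if parts[0] == "modifiers":
        if len(parts) == 2 and parts[1] in _SCALAR_MOD_FIELDS:
            return dataclasses.replace(modifiers, **{parts[1]: value}), fiscal
        if len(parts) == 3 and parts[1] in {"rr_mortality", "rr_mortality_elderly"}:
            rr_map = getattr(modifiers, parts[1])
            if rr_map is None:
                raise KeyError(f"unknown parameter path {path!r} (map not set)")
            cat = BMICategory(parts[2])
            new_map = dict(rr_map)
            new_map[cat] = value
            return dataclasses.replace(modifiers, **{parts[1]: new_map}), fiscal
    raise KeyError(f"unknown parameter path {path!r}")


def default_owsa_specs(
    modifiers: ModifierSet, fiscal: FiscalParams, rel: float = 0.2
) -> list[OwsaSpec]:
    """+-``rel`` ranges around base values for every scalar model parameter.

    Relative-risk entries vary the excess risk (RR - 1) rather than the
    RR itself so that a null association stays null.
    """
    specs: list[OwsaSpec] = []
    for name in ("tax_wedge", "vat_rate", "pension_benefit", "sickpay_fraction"):
        base = float(getattr(fiscal, name))
        lo, hi = sorted((base * (1 - rel), base * (1 + rel)))
        specs.append(OwsaSpec(f"fiscal.{name}", lo, hi))
    for name in _SCALAR_MOD_FIELDS:
        value = getattr(modifiers, name)
        if isinstance(value, Mapping):
            continue  # sex-specific values: supply explicit specs instead
        base = float(value)
        if name.startswith("hr_"):
            lo, hi = sorted((1 + (base - 1) * (1 - rel), 1 + (base - 1) * (1 + rel)))
        else:
            lo, hi = sorted((base * (1 - rel), base * (1 + rel)))
        specs.append(OwsaSpec(f"modifiers.{name}", lo, hi))
    for cat, rr in modifiers.rr_mortality.items():
        if cat == BMICategory.normal:
            continue
        excess = rr - 1.0
        lo, hi = sorted((1 + excess * (1 - rel), 1 + excess * (1 + rel)))
        specs.append(OwsaSpec(f"modifiers.rr_mortality.{cat.value}", lo, hi))
    return specs


def run_owsa(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    specs: Sequence[OwsaSpec],
    options: RunOptions | None = None,
) -> pd.DataFrame:
    """Tornado table: burden total at each spec's low and high value.

    The first row is the unperturbed base run; the remaining rows are
    sorted by bar width (|burden_high - burden_low|) descending.
    """
    options = options or RunOptions()
    base_total = evaluate_burden(strata, modifiers, fiscal, options).total
    rows = []
    for spec in specs:
        mods_lo, fis_lo = _set_param(modifiers, fiscal, spec.parameter, spec.low)
        mods_hi, fis_hi = _set_param(modifiers, fiscal, spec.parameter, spec.high)
        total_lo = evaluate_burden(strata, mods_lo, fis_lo, options).total
        total_hi = evaluate_burden(strata, mods_hi, fis_hi, options).total
        rows.append(
            {
                "parameter": spec.parameter,
                "low": spec.low,
                "high": spec.high,
                "burden_low": total_lo,
                "burden_high": total_hi,
                "width": abs(total_hi - total_lo),
            }
        )
    rows.sort(key=lambda r: r["width"], reverse=True)
    base_row = {
        "parameter": "base",
        "low": float("nan"),
        "high": float("nan"),
        "burden_low": base_total,
        "burden_high": base_total,
        "width": 0.0,
    }
    return pd.DataFrame([base_row] + rows)


def table2_battery() -> list[ScenarioSpec]:
    """The standard scenario battery for the annual prevalence model."""
    return [
        ScenarioSpec("base_case_18_70", {}),
        ScenarioSpec("age_18_65", {"age_range": (18, 65)}),
        ScenarioSpec("age_18_75", {"age_range": (18, 75)}),
        ScenarioSpec("age_18_104", {"age_range": (18, 104)}),
        ScenarioSpec("obesity_bmi30", {"oao_set": OAO_WHO}),
        ScenarioSpec("alternate_elderly_mortality", {"use_elderly_rr": True}),
        ScenarioSpec("sickleave_ft_and_pt", {"sickleave_scope": "ft_and_pt"}),
        ScenarioSpec("male_only", {"sex_filter": Sex.male}),
        ScenarioSpec("female_only", {"sex_filter": Sex.female}),
    ]


_OPTION_KEYS = {
    "age_range",
    "oao_set",
    "sickleave_scope",
    "sex_filter",
    "use_elderly_rr",
    "mortality_affects_flows",
    "grow_mepc",
    "grow_pension",
}


def apply_overrides(options: RunOptions, overrides: Mapping[str, Any]) -> RunOptions:
    unknown = set(overrides) - _OPTION_KEYS
    if unknown:
        raise KeyError(f"unknown scenario override key(s): {sorted(unknown)}")
    return dataclasses.replace(options, **dict(overrides))


def run_scenarios(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    specs: Sequence[ScenarioSpec],
    options: RunOptions | None = None,
) -> pd.DataFrame:
    """Run each scenario end-to-end; columns mirror the standard layout.

    ``net_fiscal_effect = tax_revenue_loss + transfer_spending`` holds
    for every row by construction of the burden decomposition.
    """
    options = options or RunOptions()
    rows = []
    for spec in specs:
        opt = apply_overrides(options, spec.overrides)
        result = evaluate_burden(strata, modifiers, fiscal, opt)
        rows.append(
            {
                "name": spec.name,
                "tax_revenue_loss": result.tax_loss,
                "transfer_spending": result.transfer_spending,
                "net_fiscal_effect": result.total,
            }
        )
    return pd.DataFrame(rows)
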