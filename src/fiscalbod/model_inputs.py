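"""Domain types, table readers/writers, config parsing and validation.

Every quantity the fiscal burden-of-disease model consumes is represented
here: the BMI-stratified population (one :class:`PopulationStratum` per
age-band/sex cell), the set of overweight/obesity (OAO) effect modifiers
(:class:`ModifierSet`), the fiscal constants (:class:`FiscalParams`), life
tables and the run options that select a scenario.

All monetary values are stored internally in JPY per person per year (or
JPY per year for aggregates); USD is a reporting-time conversion only.
"""

from __future__ import annotations

import configparser
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("fiscalbod")

__all__ = [
    "Sex",
    "BMICategory",
    "CATEGORIES",
    "BMI_BOUNDS",
    "OAO_JAPAN",
    "OAO_WHO",
    "PopulationStratum",
    "ModifierSet",
    "ResolvedModifiers",
    "FiscalParams",
    "LifeTable",
    "FiscalFlows",
    "BurdenResult",
    "RunOptions",
    "SchemaError",
    "InputValidationError",
    "DomainError",
    "ValidationIssue",
    "ValidationReport",
    "STRATUM_COLUMNS",
    "read_stratum_table",
    "write_stratum_table",
    "read_life_tables",
    "write_life_tables",
    "read_projection_table",
    "load_config",
    "write_config",
    "validate_inputs",
]


class Sex(str, Enum):
    male = "male"
    female = "female"


class BMICategory(str, Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


CATEGORIES: tuple[BMICategory, ...] = (
    BMICategory.underweight,
    BMICategory.normal,
    BMICategory.overweight,
    BMICategory.obese,
)

#: BMI bounds (kg/m^2), lower inclusive / upper exclusive; the four
#: categories partition [0, inf).
BMI_BOUNDS: dict[BMICategory, tuple[float, float]] = {
    BMICategory.underweight: (0.0, 18.5),
    BMICategory.normal: (18.5, 25.0),
    BMICategory.overweight: (25.0, 30.0),
    BMICategory.obese: (30.0, math.inf),
}

#: OAO under the Japanese categorisation: BMI >= 25.
OAO_JAPAN: frozenset[BMICategory] = frozenset(
    {BMICategory.overweight, BMICategory.obese}
)
#: OAO under the WHO categorisation: BMI >= 30 (scenario use).
OAO_WHO: frozenset[BMICategory] = frozenset({BMICategory.obese})


class SchemaError(ValueError):
    """A table or config file is structurally malformed (missing column/key)."""


class InputValidationError(ValueError):
    """A table or config value violates a model invariant."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


# --------------------------------------------------------------------------
# Core value objects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationStratum:
    """One (age band, sex) population cell of the prevalence model.

    Age bands are closed on both ends ([age_lo, age_hi] in whole years).
    ``bmi_proportions`` is a simplex over the four BMI categories;
    employment, sick-leave, retirement and mortality fields are annual
    probabilities; incomes and medical expenditure per capita (MEPC) are
    JPY/person/year.
    """

    age_lo: int
    age_hi: int
    sex: Sex
    count: float
    bmi_proportions: Mapping[BMICategory, float]
    emp_ft: float
    emp_pt: float
    income_ft: float
    income_pt: float
    sickleave_rate: float
    retirement_rate: float
    mepc: float
    mortality_rate: float

    @property
    def key(self) -> tuple[int, int, Sex]:
        return (self.age_lo, self.age_hi, self.sex)

    def oao_share(self, oao_set: frozenset[BMICategory] = OAO_JAPAN) -> float:
        return sum(self.bmi_proportions[k] for k in oao_set)


def _pooled(value: float | Mapping[Sex, float], sex: Sex) -> float:
    """Resolve an optionally sex-specific scalar field."""
    if isinstance(value, Mapping):
        if sex in value:
            return float(value[sex])
        if "pooled" in value:  # type: ignore[comparison-overlap]
            return float(value["pooled"])  # type: ignore[index]
        raise KeyError(f"no value for sex {sex!r} and no pooled fallback")
    return float(value)


@dataclass(frozen=True)
class ResolvedModifiers:
    """A :class:`ModifierSet` with sex-specific fields resolved to scalars."""

    beta_employment: float
    beta_income: float
    hr_sickleave: float
    hr_retirement: float
    rr_mortality: Mapping[BMICategory, float]
    rr_mortality_elderly: Mapping[BMICategory, float] | None
    af_healthcare: float

    def rr_for_age(self, age_lo: int, use_elderly: bool) -> Mapping[BMICategory, float]:
        """Relative-risk map applicable to a band starting at ``age_lo``.

        The alternate elderly map (when present and enabled) replaces the
        base map for bands whose lower bound is at least 65.
        """
        if use_elderly and self.rr_mortality_elderly is not None and age_lo >= 65:
            return self.rr_mortality_elderly
        return self.rr_mortality


def _unit_rr() -> dict[BMICategory, float]:
    return {k: 1.0 for k in CATEGORIES}


@dataclass(frozen=True)
class ModifierSet:
    """OAO-vs-reference effect sizes.

    ``beta_employment`` is additive on the employment-probability scale
    (a regression marginal effect); ``beta_income`` is a relative wage
    effect; hazard ratios multiply baseline sick-leave/retirement rates;
    ``rr_mortality`` maps each BMI category to an all-cause mortality
    relative risk with normal weight as reference (RR = 1);
    ``af_healthcare`` is the fraction of total medical spend attributable
    to OAO. Scalar fields may be given per sex as a mapping.
    """

    beta_employment: float | Mapping[Sex, float] = 0.0
    beta_income: float | Mapping[Sex, float] = 0.0
    hr_sickleave: float | Mapping[Sex, float] = 1.0
    hr_retirement: float | Mapping[Sex, float] = 1.0
    rr_mortality: Mapping[BMICategory, float] = field(default_factory=_unit_rr)
    rr_mortality_elderly: Mapping[BMICategory, float] | None = None
    af_healthcare: float | Mapping[Sex, float] = 0.0

    def for_sex(self, sex: Sex) -> ResolvedModifiers:
        return ResolvedModifiers(
            beta_employment=_pooled(self.beta_employment, sex),
            beta_income=_pooled(self.beta_income, sex),
            hr_sickleave=_pooled(self.hr_sickleave, sex),
            hr_retirement=_pooled(self.hr_retirement, sex),
            rr_mortality=dict(self.rr_mortality),
            rr_mortality_elderly=(
                dict(self.rr_mortality_elderly)
                if self.rr_mortality_elderly is not None
                else None
            ),
            af_healthcare=_pooled(self.af_healthcare, sex),
        )

    @staticmethod
    def null() -> "ModifierSet":
        """Modifiers under which OAO has no effect at all."""
        return ModifierSet()


@dataclass(frozen=True)
class FiscalParams:
    """Fiscal constants of the government-accounts model.

    tax_wedge
        Fraction of labor cost collected as direct tax (single multiplier).
    vat_rate
        Consumption-tax rate applied to disposable income and transfers.
    pension_benefit
        JPY/person/year paid to a retired individual.
    sickpay_fraction
        Fraction of salary received while on sick leave (default 2/3, the
        Japanese sickness-allowance replacement rate).
    prevalence_growth
        Annual relative growth of the combined OAO share, by sex.
    """

    tax_wedge: float = 0.327
    vat_rate: float = 0.10
    pension_benefit: float = 790_000.0
    sickpay_fraction: float = 2.0 / 3.0
    discount_rate: float = 0.02
    wage_growth: float = 0.02
    prevalence_growth: Mapping[Sex, float] = field(
        default_factory=lambda: {Sex.male: 0.0147, Sex.female: 0.0047}
    )
    horizon_years: int = 10
    yen_per_usd: float = 143.58

    def growth_for(self, sex: Sex) -> float:
        return float(self.prevalence_growth[sex])


@dataclass(frozen=True)
class LifeTable:
    """Single-year-of-age period life table for one sex.

    ``qx[a]`` is the probability of dying between exact ages a and a+1;
    the terminal age has qx = 1.
    """

    sex: Sex
    qx: Mapping[int, float]
    terminal_age: int

    def __post_init__(self) -> None:
        missing = [a for a in range(0, self.terminal_age + 1) if a not in self.qx]
        if missing:
            raise InputValidationError(
                f"life table ({self.sex.value}) missing qx for ages {missing[:5]}..."
                if len(missing) > 5
                else f"life table ({self.sex.value}) missing qx for ages {missing}"
            )
        if abs(self.qx[self.terminal_age] - 1.0) > 1e-12:
            raise InputValidationError(
                f"life table ({self.sex.value}): qx at terminal age "
                f"{self.terminal_age} must be 1"
            )

    def annual_qx(self, age: int) -> float:
        if age < 0 or age > self.terminal_age:
            raise DomainError(
                f"age {age} outside life table range 0..{self.terminal_age}"
            )
        return float(self.qx[age])

    def band_qx(self, age_lo: int, age_hi: int) -> float:
        """Unweighted mean of single-year qx over a closed band."""
        if age_lo > age_hi:
            raise DomainError(f"empty band [{age_lo}, {age_hi}]")
        if age_hi > self.terminal_age or age_lo < 0:
            raise DomainError(
                f"band [{age_lo}, {age_hi}] outside life table range "
                f"0..{self.terminal_age}"
            )
        ages = range(age_lo, age_hi + 1)
        return sum(self.qx[a] for a in ages) / len(ages)


@dataclass(frozen=True)
class FiscalFlows:
    """Annual government flows: taxes in, transfers and healthcare out.

    ``net = direct_tax + indirect_tax - transfers - healthcare``.
    """

    direct_tax: float
    indirect_tax: float
    transfers: float
    healthcare: float
    net: float

    @classmethod
    def from_components(
        cls,
        direct_tax: float,
        indirect_tax: float,
        transfers: float,
        healthcare: float,
    ) -> "FiscalFlows":
        return cls(
            direct_tax=direct_tax,
            indirect_tax=indirect_tax,
            transfers=transfers,
            healthcare=healthcare,
            net=direct_tax + indirect_tax - transfers - healthcare,
        )

    def __add__(self, other: "FiscalFlows") -> "FiscalFlows":
        return FiscalFlows.from_components(
            self.direct_tax + other.direct_tax,
            self.indirect_tax + other.indirect_tax,
            self.transfers + other.transfers,
            self.healthcare + other.healthcare,
        )

    @classmethod
    def zero(cls) -> "FiscalFlows":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class BurdenResult:
    """Control-minus-intervention fiscal difference, burden-positive signs.

    ``direct_tax_loss`` and ``indirect_tax_loss`` are revenue the
    government forgoes because of OAO; ``transfer_excess`` (pensions) and
    ``healthcare_excess`` are extra spending it incurs.
    ``total`` is the sum of the four components.
    """

    direct_tax_loss: float
    indirect_tax_loss: float
    transfer_excess: float
    healthcare_excess: float
    total: float
    by_stratum: Mapping[tuple[int, int, Sex], "BurdenResult"] | None = None
    currency: str = "JPY"

    @classmethod
    def from_components(
        cls,
        direct_tax_loss: float,
        indirect_tax_loss: float,
        transfer_excess: float,
        healthcare_excess: float,
        currency: str = "JPY",
    ) -> "BurdenResult":
        return cls(
            direct_tax_loss=direct_tax_loss,
            indirect_tax_loss=indirect_tax_loss,
            transfer_excess=transfer_excess,
            healthcare_excess=healthcare_excess,
            total=direct_tax_loss
            + indirect_tax_loss
            + transfer_excess
            + healthcare_excess,
            currency=currency,
        )

    @property
    def tax_loss(self) -> float:
        """Combined direct + indirect tax revenue loss."""
        return self.direct_tax_loss + self.indirect_tax_loss

    @property
    def transfer_spending(self) -> float:
        """Combined excess transfer (pension) + healthcare spending."""
        return self.transfer_excess + self.healthcare_excess


@dataclass(frozen=True)
class RunOptions:
    """Options selecting a model variant / scenario.

    age_range
        Closed age interval; strata whose band overlaps it are included.
    oao_set
        Categories reassigned to normal weight in the counterfactual.
    sickleave_scope
        ``"ft_only"`` (base case) or ``"ft_and_pt"``.
    sex_filter
        When set, the other sex's counts are zeroed (shapes preserved).
    use_elderly_rr
        Use the alternate mortality relative risks for bands from age 65.
    mortality_affects_flows
        Remove half a person-year per OAO-attributable death from the
        OAO group's labor and transfer flows (mid-year convention).
    grow_mepc / grow_pension
        Whether medical expenditure and pension benefit follow wage
        growth over the projection horizon.
    """

    age_range: tuple[int, int] = (18, 70)
    oao_set: frozenset[BMICategory] = OAO_JAPAN
    sickleave_scope: str = "ft_only"
    sex_filter: Sex | None = None
    use_elderly_rr: bool = False
    mortality_affects_flows: bool = True
    grow_mepc: bool = True
    grow_pension: bool = True


# --------------------------------------------------------------------------
# Table I/O
# --------------------------------------------------------------------------

STRATUM_COLUMNS = [
    "age_lo",
    "age_hi",
    "sex",
    "count",
    "p_under",
    "p_normal",
    "p_over",
    "p_obese",
    "emp_ft",
    "emp_pt",
    "income_ft",
    "income_pt",
    "sickleave",
    "retirement",
    "mepc",
    "mortality",
]

_PROP_COLS = {
    "p_under": BMICategory.underweight,
    "p_normal": BMICategory.normal,
    "p_over": BMICategory.overweight,
    "p_obese": BMICategory.obese,
}


def read_stratum_table(path: str | Path) -> list[PopulationStratum]:
    """Read a population stratum table (CSV, UTF-8, header mandatory).

    Raises :class:`SchemaError` on a missing column and
    :class:`InputValidationError` (naming the row) when BMI proportions
    do not form a simplex or age bands overlap within a sex.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STRATUM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"stratum table {path}: missing column(s) {missing}")

    strata: list[PopulationStratum] = []
    for idx, row in df.iterrows():
        props = {cat: float(row[col]) for col, cat in _PROP_COLS.items()}
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise InputValidationError(
                f"stratum table {path}, row {idx} "
                f"(ages {int(row['age_lo'])}-{int(row['age_hi'])}, {row['sex']}): "
                f"BMI proportions sum to {sum(props.values()):.6f}, expected 1"
            )
        strata.append(
            PopulationStratum(
                age_lo=int(row["age_lo"]),
                age_hi=int(row["age_hi"]),
                sex=Sex(row["sex"]),
                count=float(row["count"]),
                bmi_proportions=props,
                emp_ft=float(row["emp_ft"]),
                emp_pt=float(row["emp_pt"]),
                income_ft=float(row["income_ft"]),
                income_pt=float(row["income_pt"]),
                sickleave_rate=float(row["sickleave"]),
                retirement_rate=float(row["retirement"]),
                mepc=float(row["mepc"]),
                mortality_rate=float(row["mortality"]),
            )
        )

    strata.sort(key=lambda s: (s.sex.value, s.age_lo))
    for sex in Sex:
        bands = [(s.age_lo, s.age_hi) for s in strata if s.sex == sex]
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 <= hi1:
                raise InputValidationError(
                    f"stratum table {path}: overlapping age bands "
                    f"[{lo1},{hi1}] and [{lo2},{hi2}] for sex {sex.value}"
                )
            if lo2 != hi1 + 1:
                logger.warning(
                    "stratum table %s: gap between bands [%d,%d] and [%d,%d] "
                    "for sex %s",
                    path,
                    lo1,
                    hi1,
                    lo2,
                    hi2,
                    sex.value,
                )
    return strata


def write_stratum_table(strata: Sequence[PopulationStratum], path: str | Path) -> None:
    """Write strata as CSV; numeric fields round-trip exactly (repr floats)."""
    rows = []
    for s in strata:
        rows.append(
            {
                "age_lo": s.age_lo,
                "age_hi": s.age_hi,
                "sex": s.sex.value,
                "count": s.count,
                "p_under": s.bmi_proportions[BMICategory.underweight],
                "p_normal": s.bmi_proportions[BMICategory.normal],
                "p_over": s.bmi_proportions[BMICategory.overweight],
                "p_obese": s.bmi_proportions[BMICategory.obese],
                "emp_ft": s.emp_ft,
                "emp_pt": s.emp_pt,
                "income_ft": s.income_ft,
                "income_pt": s.income_pt,
                "sickleave": s.sickleave_rate,
                "retirement": s.retirement_rate,
                "mepc": s.mepc,
                "mortality": s.mortality_rate,
            }
        )
    pd.DataFrame(rows, columns=STRATUM_COLUMNS).to_csv(path, index=False)


def read_life_tables(path: str | Path) -> dict[Sex, LifeTable]:
    """Read life tables (CSV columns sex, age, qx) into one table per sex."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sex", "age", "qx"):
        if col not in df.columns:
            raise SchemaError(f"life table {path}: missing column {col!r}")
    out: dict[Sex, LifeTable] = {}
    for sex_value, grp in df.groupby("sex"):
        qx = {int(a): float(q) for a, q in zip(grp["age"], grp["qx"])}
        out[Sex(sex_value)] = LifeTable(
            sex=Sex(sex_value), qx=qx, terminal_age=max(qx)
        )
    return out


def write_life_tables(tables: Mapping[Sex, LifeTable], path: str | Path) -> None:
    rows = [
        {"sex": lt.sex.value, "age": a, "qx": lt.qx[a]}
        for lt in tables.values()
        for a in sorted(lt.qx)
    ]
    pd.DataFrame(rows, columns=["sex", "age", "qx"]).to_csv(path, index=False)


def read_projection_table(path: str | Path) -> pd.DataFrame:
    """Read an optional population-projection table (year, sex, age_lo, age_hi, count)."""
    df = pd.read_csv(path)
    needed = ["year", "sex", "age_lo", "age_hi", "count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"projection table {path}: missing column(s) {missing}")
    return df


# --------------------------------------------------------------------------
# Config parsing
# --------------------------------------------------------------------------

_FISCAL_KEYS = {
    "tax_wedge",
    "vat_rate",
    "pension_benefit",
    "sickpay_fraction",
    "discount_rate",
    "wage_growth",
    "prevalence_growth_male",
    "prevalence_growth_female",
    "horizon_years",
    "yen_per_usd",
}

_MODIFIER_SCALARS = ("beta_employment", "beta_income", "hr_sickleave", "hr_retirement", "af_healthcare")

_RUN_KEYS = {
    "age_lo",
    "age_hi",
    "oao",
    "sickleave_scope",
    "sex_filter",
    "use_elderly_rr",
    "mortality_affects_flows",
    "grow_mepc",
    "grow_pension",
}


def _sexed_scalar(
    section: Mapping[str, str], base: str
) -> float | dict[Sex, float] | None:
    """Read ``base`` or the sex-specific pair ``base_male``/``base_female``."""
    per_sex = {
        sex: float(section[f"{base}_{sex.value}"])
        for sex in Sex
        if f"{base}_{sex.value}" in section
    }
    if per_sex:
        if base in section:
            per_sex["pooled"] = float(section[base])  # type: ignore[index]
        return per_sex
    if base in section:
        return float(section[base])
    return None


def load_config(path: str | Path) -> tuple[FiscalParams, ModifierSet, RunOptions]:
    """Parse a config file with sections [fiscal], [modifiers], [run].

    Unspecified keys take the documented defaults; unknown keys are logged
    as warnings (not fatal); out-of-range values raise
    :class:`InputValidationError`.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise SchemaError(f"config file not found or unreadable: {path}")

    fiscal_sec = parser["fiscal"] if parser.has_section("fiscal") else {}
    mod_sec = parser["modifiers"] if parser.has_section("modifiers") else {}
    run_sec = parser["run"] if parser.has_section("run") else {}

    # -- fiscal --------------------------------------------------------
    defaults = FiscalParams()
    growth = dict(defaults.prevalence_growth)
    for sex in Sex:
        key = f"prevalence_growth_{sex.value}"
        if key in fiscal_sec:
            growth[sex] = float(fiscal_sec[key])
    fiscal = FiscalParams(
        tax_wedge=float(fiscal_sec.get("tax_wedge", defaults.tax_wedge)),
        vat_rate=float(fiscal_sec.get("vat_rate", defaults.vat_rate)),
        pension_benefit=float(
            fiscal_sec.get("pension_benefit", defaults.pension_benefit)
        ),
        sickpay_fraction=float(
            fiscal_sec.get("sickpay_fraction", defaults.sickpay_fraction)
        ),
        discount_rate=float(fiscal_sec.get("discount_rate", defaults.discount_rate)),
        wage_growth=float(fiscal_sec.get("wage_growth", defaults.wage_growth)),
        prevalence_growth=growth,
        horizon_years=int(fiscal_sec.get("horizon_years", defaults.horizon_years)),
        yen_per_usd=float(fiscal_sec.get("yen_per_usd", defaults.yen_per_usd)),
    )
    for key in fiscal_sec:
        if key not in _FISCAL_KEYS:
            logger.warning("config %s: unknown [fiscal] key %r ignored", path, key)

    # -- modifiers -----------------------------------------------------
    rr: dict[BMICategory, float] = _unit_rr()
    rr_elderly: dict[BMICategory, float] = {}
    known_mod_keys: set[str] = set()
    for base in _MODIFIER_SCALARS:
        known_mod_keys.update({base, f"base_{base}"})
        for sex in Sex:
            known_mod_keys.add(f"{base}_{sex.value}")
    short = {
        "under": BMICategory.underweight,
        "normal": BMICategory.normal,
        "overweight": BMICategory.overweight,
        "obese": BMICategory.obese,
    }
    for name, cat in short.items():
        k = f"rr_mortality_{name}"
        known_mod_keys.add(k)
        if k in mod_sec:
            rr[cat] = float(mod_sec[k])
        k = f"rr_mortality_elderly_{name}"
        known_mod_keys.add(k)
        if k in mod_sec:
            rr_elderly[cat] = float(mod_sec[k])
    if rr_elderly:
        full_elderly = _unit_rr()
        full_elderly.update(rr_elderly)
    for key in mod_sec:
        if key not in known_mod_keys:
            logger.warning("config %s: unknown [modifiers] key %r ignored", path, key)

    def _mod(base: str, default: float) -> float | dict[Sex, float]:
        v = _sexed_scalar(mod_sec, base)
        return default if v is None else v

    modifiers = ModifierSet(
        beta_employment=_mod("beta_employment", 0.0),
        beta_income=_mod("beta_income", 0.0),
        hr_sickleave=_mod("hr_sickleave", 1.0),
        hr_retirement=_mod("hr_retirement", 1.0),
        rr_mortality=rr,
        rr_mortality_elderly=full_elderly if rr_elderly else None,
        af_healthcare=_mod("af_healthcare", 0.0),
    )

    # -- run options ---------------------------------------------------
    oao_names = run_sec.get("oao", "overweight,obese")
    oao_set = frozenset(BMICategory(n.strip()) for n in oao_names.split(","))
    sexf = run_sec.get("sex_filter", "").strip() or None
    options = RunOptions(
        age_range=(
            int(run_sec.get("age_lo", 18)),
            int(run_sec.get("age_hi", 70)),
        ),
        oao_set=oao_set,
        sickleave_scope=run_sec.get("sickleave_scope", "ft_only"),
        sex_filter=Sex(sexf) if sexf else None,
        use_elderly_rr=_parse_bool(run_sec.get("use_elderly_rr", "false")),
        mortality_affects_flows=_parse_bool(
            run_sec.get("mortality_affects_flows", "true")
        ),
        grow_mepc=_parse_bool(run_sec.get("grow_mepc", "true")),
        grow_pension=_parse_bool(run_sec.get("grow_pension", "true")),
    )
    for key in run_sec:
        if key not in _RUN_KEYS:
            logger.warning("config %s: unknown [run] key %r ignored", path, key)

    report = _validate_params(fiscal, modifiers, options)
    if report.issues:
        raise InputValidationError(
            f"config {path}: "
            + "; ".join(f"{i.location}: {i.message}" for i in report.issues)
        )
    return fiscal, modifiers, options


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"1", "true", "yes", "on"}:
        return True
    if t in {"0", "false", "no", "off"}:
        return False
    raise InputValidationError(f"cannot parse boolean value {text!r}")


def write_config(
    fiscal: FiscalParams,
    modifiers: ModifierSet,
    options: RunOptions,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a config file that :func:`load_config` reads back identically."""
    parser = configparser.ConfigParser()
    parser["fiscal"] = {
        "tax_wedge": repr(fiscal.tax_wedge),
        "vat_rate": repr(fiscal.vat_rate),
        "pension_benefit": repr(fiscal.pension_benefit),
        "sickpay_fraction": repr(fiscal.sickpay_fraction),
        "discount_rate": repr(fiscal.discount_rate),
        "wage_growth": repr(fiscal.wage_growth),
        "prevalence_growth_male": repr(fiscal.growth_for(Sex.male)),
        "prevalence_growth_female": repr(fiscal.growth_for(Sex.female)),
        "horizon_years": str(fiscal.horizon_years),
        "yen_per_usd": repr(fiscal.yen_per_usd),
    }
    mod: dict[str, str] = {}
    for base in _MODIFIER_SCALARS:
        value = getattr(modifiers, base)
        if isinstance(value, Mapping):
            for sex in Sex:
                if sex in value:
                    mod[f"{base}_{sex.value}"] = repr(float(value[sex]))
            if "pooled" in value:  # type: ignore[comparison-overlap]
                mod[base] = repr(float(value["pooled"]))  # type: ignore[index]
        else:
            mod[base] = repr(float(value))
    short = {
        BMICategory.underweight: "under",
        BMICategory.normal: "normal",
        BMICategory.overweight: "overweight",
        BMICategory.obese: "obese",
    }
    for cat, name in short.items():
        mod[f"rr_mortality_{name}"] = repr(float(modifiers.rr_mortality[cat]))
        if modifiers.rr_mortality_elderly is not None:
            mod[f"rr_mortality_elderly_{name}"] = repr(
                float(modifiers.rr_mortality_elderly[cat])
            )
    parser["modifiers"] = mod
    parser["run"] = {
        "age_lo": str(options.age_range[0]),
        "age_hi": str(options.age_range[1]),
        "oao": ",".join(sorted(c.value for c in options.oao_set)),
        "sickleave_scope": options.sickleave_scope,
        "sex_filter": options.sex_filter.value if options.sex_filter else "",
        "use_elderly_rr": str(options.use_elderly_rr).lower(),
        "mortality_affects_flows": str(options.mortality_affects_flows).lower(),
        "grow_mepc": str(options.grow_mepc).lower(),
        "grow_pension": str(options.grow_pension).lower(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        parser.write(fh)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    location: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"{i.location}: {i.message}" for i in self.issues)


def _prob(x: float) -> bool:
    return 0.0 <= x <= 1.0


def _validate_params(
    fiscal: FiscalParams, modifiers: ModifierSet, options: RunOptions
) -> ValidationReport:
    issues: list[ValidationIssue] = []

    def bad(loc: str, msg: str) -> None:
        issues.append(ValidationIssue(loc, msg))

    if not 0.0 <= fiscal.tax_wedge < 1.0:
        bad("fiscal.tax_wedge", f"must be in [0,1), got {fiscal.tax_wedge}")
    if not 0.0 <= fiscal.vat_rate < 1.0:
        bad("fiscal.vat_rate", f"must be in [0,1), got {fiscal.vat_rate}")
    if not 0.0 <= fiscal.sickpay_fraction <= 1.0:
        bad(
            "fiscal.sickpay_fraction",
            f"must be in [0,1], got {fiscal.sickpay_fraction}",
        )
    if fiscal.pension_benefit < 0:
        bad("fiscal.pension_benefit", "must be non-negative")
    if fiscal.horizon_years < 1:
        bad("fiscal.horizon_years", f"must be >= 1, got {fiscal.horizon_years}")
    if fiscal.yen_per_usd <= 0:
        bad("fiscal.yen_per_usd", "must be positive")

    for sex in Sex:
        res = modifiers.for_sex(sex)
        if res.hr_sickleave < 0:
            bad(f"modifiers.hr_sickleave[{sex.value}]", "hazard ratio must be >= 0")
        if res.hr_retirement < 0:
            bad(f"modifiers.hr_retirement[{sex.value}]", "hazard ratio must be >= 0")
        if not 0.0 <= res.af_healthcare < 1.0:
            bad(
                f"modifiers.af_healthcare[{sex.value}]",
                f"attributable fraction must be in [0,1), got {res.af_healthcare}",
            )
    for name, rr_map in (
        ("rr_mortality", modifiers.rr_mortality),
        ("rr_mortality_elderly", modifiers.rr_mortality_elderly),
    ):
        if rr_map is None:
            continue
        if abs(rr_map.get(BMICategory.normal, 1.0) - 1.0) > 1e-12:
            bad(
                f"modifiers.{name}[normal]",
                "reference category (normal weight) must have RR = 1",
            )
        for cat, rr in rr_map.items():
            if rr < 0:
                bad(f"modifiers.{name}[{cat.value}]", "relative risk must be >= 0")

    if options.sickleave_scope not in {"ft_only", "ft_and_pt"}:
        bad("run.sickleave_scope", f"unknown scope {options.sickleave_scope!r}")
    if options.age_range[0] > options.age_range[1]:
        bad("run.age_range", f"empty age range {options.age_range}")
    return ValidationReport(tuple(issues))


def validate_inputs(
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    life_tables: Mapping[Sex, LifeTable] | None = None,
    options: RunOptions | None = None,
) -> ValidationReport:
    """Check every model invariant; returns a report (never raises).

    The report lists each breach with row/field coordinates and is empty
    iff all invariants hold. The function is idempotent and side-effect
    free.
    """
    report = _validate_params(fiscal, modifiers, options or RunOptions())
    issues = list(report.issues)

    def bad(loc: str, msg: str) -> None:
        issues.append(ValidationIssue(loc, msg))

    for s in strata:
        loc = f"stratum[{s.age_lo}-{s.age_hi},{s.sex.value}]"
        total = sum(s.bmi_proportions[k] for k in CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            bad(loc, f"BMI proportions sum to {total:.9f}, expected 1")
        for k in CATEGORIES:
            if s.bmi_proportions[k] < -1e-12:
                bad(loc, f"negative proportion for {k.value}")
        for fname in ("emp_ft", "emp_pt", "sickleave_rate", "retirement_rate", "mortality_rate"):
            v = getattr(s, fname)
            if not _prob(v):
                bad(loc, f"{fname} = {v} outside [0,1]")
        if s.emp_ft + s.emp_pt > 1.0 + 1e-9:
            bad(loc, f"emp_ft + emp_pt = {s.emp_ft + s.emp_pt:.6f} exceeds 1")
        if s.count < 0:
            bad(loc, f"negative count {s.count}")
        for fname in ("income_ft", "income_pt", "mepc"):
            if getattr(s, fname) < 0:
                bad(loc, f"negative {fname}")
        if s.age_lo > s.age_hi:
            bad(loc, "age_lo exceeds age_hi")
        if life_tables is not None:
            lt = life_tables.get(s.sex)
            if lt is None:
                bad(loc, f"no life table for sex {s.sex.value}")
            elif s.age_hi > lt.terminal_age:
                bad(loc, f"band exceeds life table terminal age {lt.terminal_age}")
    return ValidationReport(tuple(issues))
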