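"""Synthetic input generation.

The model's real inputs (national survey BMI prevalence, labor-force
statistics, expenditure tables, life tables) are aggregated government
statistics that cannot be redistributed, so this module builds complete,
statistically plausible stand-ins:

* :func:`generate_parameter_set` — a seeded random input set with the
  qualitative shape of the real data: BMI prevalence rising with age to
  a midlife plateau (logistic ramp), hump-shaped employment and income
  age profiles, Gompertz-like mortality.
* :func:`japan_like_fixture` — one fixed, no-randomness calibration at
  Japan-2023-like magnitudes (working-age population about 7.5e7,
  overall OAO prevalence about 0.25). Quantities that are published —
  the 10% VAT, 0.327 tax wedge, 2% discount and wage growth, 1.47%/0.47%
  annual OAO prevalence growth for men/women, age range 18-70 — are used
  verbatim; everything else is synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model_inputs import (
    BMICategory,
    FiscalParams,
    LifeTable,
    ModifierSet,
    PopulationStratum,
    RunOptions,
    Sex,
    write_config,
    write_life_tables,
    write_stratum_table,
)

__all__ = [
    "GeneratorSpec",
    "generate_parameter_set",
    "japan_like_fixture",
    "write_parameter_set",
    "default_age_bands",
]

TERMINAL_AGE = 104


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the synthetic-input generator.

    ``oao_prevalence_level`` is the target combined overweight+obese
    proportion at midlife (pooled over sexes); ``employment_peak`` the
    peak full-time employment probability; ``income_scale`` the peak
    mean full-time income (JPY/year); ``mortality_shape`` the Gompertz
    slope of the synthetic life table.
    """

    seed: int = 0
    n_age_bands: int = 18
    oao_prevalence_level: float = 0.30
    employment_peak: float = 0.75
    income_scale: float = 4_200_000.0
    mortality_shape: float = 0.095

    def __post_init__(self) -> None:
        if not 0.0 < self.oao_prevalence_level < 1.0:
            raise ValueError("oao_prevalence_level must be in (0,1)")
        if self.income_scale <= 0 or self.employment_peak <= 0 or self.mortality_shape <= 0:
            raise ValueError("scales must be positive")
        if not 1 <= self.n_age_bands <= 18:
            raise ValueError("n_age_bands must be in 1..18")


def default_age_bands(n_bands: int = 18) -> list[tuple[int, int]]:
    """Closed age bands (18-19, 20-24, ..., 100-104), first ``n_bands`` of them."""
    bands = [(18, 19)] + [(lo, lo + 4) for lo in range(20, 101, 5)]
    return bands[:n_bands]


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _build_life_tables(shape: float) -> dict[Sex, LifeTable]:
    """Gompertz-like qx = background + A exp(shape * age), capped at 1."""
    tables = {}
    for sex, level in ((Sex.male, 1.55e-5), (Sex.female, 8.5e-6)):
        qx = {}
        for age in range(0, TERMINAL_AGE + 1):
            qx[age] = min(1.0, 2.0e-4 + level * math.exp(shape * age))
        qx[TERMINAL_AGE] = 1.0
        tables[sex] = LifeTable(sex=sex, qx=qx, terminal_age=TERMINAL_AGE)
    return tables


def _base_modifiers() -> ModifierSet:
    """Plausible effect sizes for the fixed calibration.

    Employment marginal effect and the attributable fraction dominate in
    magnitude, mirroring the usual finding that labor-market channels
    outweigh healthcare attribution in fiscal models of obesity.
    """
    return ModifierSet(
        beta_employment=-0.035,
        beta_income=-0.02,
        hr_sickleave=1.3,
        hr_retirement=1.3,
        rr_mortality={
            BMICategory.underweight: 1.2,
            BMICategory.normal: 1.0,
            BMICategory.overweight: 1.05,
            BMICategory.obese: 1.35,
        },
        rr_mortality_elderly={
            BMICategory.underweight: 1.35,
            BMICategory.normal: 1.0,
            BMICategory.overweight: 1.0,
            BMICategory.obese: 1.25,
        },
        af_healthcare=0.04,
    )


def _base_fiscal() -> FiscalParams:
    return FiscalParams()  # defaults carry the published constants


def _prevalence(
    mid: float, sex: Sex, level: float, jitter: float
) -> dict[BMICategory, float]:
    """Logistic age ramp with sex-specific asymptote, OAO split 3:1."""
    asym = level * (1.18 if sex == Sex.male else 0.82) / 0.82
    p_oao = asym * _logistic((mid - 35.0) / 8.0) * (1.0 + jitter)
    p_oao = min(max(p_oao, 0.01), 0.6)
    p_obese = 0.25 * p_oao
    p_over = 0.75 * p_oao
    p_under_base = 0.045 if sex == Sex.male else 0.09
    p_under = max(0.01, p_under_base * (1.0 - 0.004 * max(mid - 20.0, 0.0)))
    p_normal = 1.0 - p_oao - p_under
    return {
        BMICategory.underweight: p_under,
        BMICategory.normal: p_normal,
        BMICategory.overweight: p_over,
        BMICategory.obese: p_obese,
    }


def _employment(mid: float, sex: Sex, peak: float) -> tuple[float, float]:
    shape = math.exp(-(((mid - 45.0) / 24.0) ** 2))
    cutoff = _logistic((68.0 - mid) / 3.0)  # winds employment down past ~68
    if sex == Sex.male:
        ft = peak * 1.08 * shape * cutoff
        pt = 0.07 * shape * cutoff
    else:
        ft = peak * 0.78 * shape * cutoff
        pt = 0.20 * shape * cutoff
    ft = min(ft, 0.95)
    if ft + pt > 0.98:
        scale = 0.98 / (ft + pt)
        ft, pt = ft * scale, pt * scale
    return ft, pt


def _income(mid: float, sex: Sex, scale: float) -> tuple[float, float]:
    shape = 0.45 + 0.55 * math.exp(-(((mid - 50.0) / 22.0) ** 2))
    ft = scale * shape * (1.0 if sex == Sex.male else 0.75)
    return ft, 0.35 * ft


def _retirement(mid: float) -> float:
    """Proportion currently retired / drawing a pension."""
    if mid < 50.0:
        return 0.002
    if mid < 65.0:
        return 0.002 + 0.20 * _logistic((mid - 61.0) / 2.5)
    return min(1.0, 0.75 + 0.012 * (mid - 65.0))


def _counts(mid: float) -> float:
    """Persons per single year of age (one sex)."""
    base = 7.3e5
    if mid <= 60.0:
        return base
    return base * math.exp(-0.045 * (mid - 60.0))


def _build(
    spec: GeneratorSpec, rng: np.random.Generator | None
) -> tuple[list[PopulationStratum], ModifierSet, FiscalParams, dict[Sex, LifeTable]]:
    life_tables = _build_life_tables(spec.mortality_shape)
    bands = default_age_bands(spec.n_age_bands)

    def noise(scale: float) -> float:
        if rng is None:
            return 0.0
        return float(rng.normal(0.0, scale))

    strata: list[PopulationStratum] = []
    for sex in Sex:
        lt = life_tables[sex]
        for lo, hi in bands:
            mid = (lo + hi) / 2.0
            props = _prevalence(mid, sex, spec.oao_prevalence_level, noise(0.02))
            ft, pt = _employment(mid, sex, spec.employment_peak)
            ft = min(0.95, max(0.0, ft * (1.0 + noise(0.02))))
            y_ft, y_pt = _income(mid, sex, spec.income_scale)
            y_ft *= math.exp(noise(0.04))
            y_pt *= math.exp(noise(0.04))
            count = sum(_counts(a + 0.5) for a in range(lo, hi + 1))
            count *= 1.0 + noise(0.02)
            sick = min(1.0, max(0.0, (0.022 + 0.0003 * max(mid - 40.0, 0.0)) * (1.0 + noise(0.05))))
            strata.append(
                PopulationStratum(
                    age_lo=lo,
                    age_hi=hi,
                    sex=sex,
                    count=count,
                    bmi_proportions=props,
                    emp_ft=ft,
                    emp_pt=min(pt, 0.98 - ft),
                    income_ft=y_ft,
                    income_pt=y_pt,
                    sickleave_rate=sick,
                    retirement_rate=_retirement(mid),
                    mepc=1.2e5 * math.exp(0.025 * (mid - 20.0)) * (1.0 + noise(0.03)),
                    mortality_rate=lt.band_qx(lo, hi),
                )
            )
    return strata, _base_modifiers(), _base_fiscal(), life_tables


def generate_parameter_set(
    spec: GeneratorSpec,
) -> tuple[list[PopulationStratum], ModifierSet, FiscalParams, dict[Sex, LifeTable]]:
    """Random but structurally valid input set, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    return _build(spec, rng)


def japan_like_fixture() -> tuple[
    list[PopulationStratum], ModifierSet, FiscalParams, dict[Sex, LifeTable]
]:
    """The fixed Japan-2023-like calibration (no randomness).

    An approximate stand-in for the national inputs, not a replication
    of any published table: only the fiscal constants that are public
    (VAT, tax wedge, discounting, growth rates) are exact.
    """
    return _build(GeneratorSpec(), rng=None)


def write_parameter_set(
    out_dir: str | Path,
    strata: Sequence[PopulationStratum],
    modifiers: ModifierSet,
    fiscal: FiscalParams,
    life_tables: Mapping[Sex, LifeTable],
    options: RunOptions | None = None,
    header_comment: str = "synthetic parameter set (generated stand-in data)",
) -> dict[str, Path]:
    """Emit strata.csv, lifetable.csv and config.ini readable by model_inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "strata": out / "strata.csv",
        "lifetable": out / "lifetable.csv",
        "config": out / "config.ini",
    }
    write_stratum_table(strata, paths["strata"])
    write_life_tables(life_tables, paths["lifetable"])
    write_config(
        fiscal, modifiers, options or RunOptions(), paths["config"], header_comment
    )
    return paths
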