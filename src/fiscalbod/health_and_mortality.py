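"""Healthcare-cost attribution and OAO-attributable mortality.

Two pieces:

* redistribution of medical expenditure per capita (MEPC) across BMI
  categories given an OAO-attributable fraction of total spend, with
  exact conservation of the population mean;
* the Rockhill population attributable fraction (PAF) over BMI
  categories, Sum_k pd_k (RR_k - 1)/RR_k, combined with life tables to
  yield annual OAO-attributable deaths per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model_inputs import (
    BMICategory,
    CATEGORIES,
    DomainError,
    LifeTable,
    OAO_JAPAN,
    PopulationStratum,
    Sex,
)

__all__ = [
    "HealthCostProfile",
    "MortalityInputs",
    "adjust_mepc",
    "derive_case_distribution",
    "rockhill_paf",
    "excess_deaths",
]


@dataclass(frozen=True)
class HealthCostProfile:
    """Per-category medical expenditure consistent with a population mean.

    Invariant: the prevalence-weighted mean of ``mepc_by_category``
    equals ``mepc_gp`` (conservation of total spend).
    """

    mepc_by_category: Mapping[BMICategory, float]
    mepc_gp: float


@dataclass(frozen=True)
class MortalityInputs:
    """Case distribution and relative risks for the PAF computation.

    ``pd`` holds the proportion of deaths (cases) falling in each BMI
    category (a simplex); ``rr`` the all-cause mortality relative risk
    per category with normal weight as reference (RR = 1).
    """

    pd: Mapping[BMICategory, float]
    rr: Mapping[BMICategory, float]


def adjust_mepc(
    mepc_gp: float,
    prevalence: Mapping[BMICategory, float],
    af: float,
    oao_set: frozenset[BMICategory] = OAO_JAPAN,
) -> HealthCostProfile:
    """Split population MEPC into per-category values via an attributable fraction.

    The non-OAO categories are costed at ``(1 - af) * mepc_gp``; the OAO
    categories additionally carry the attributable share ``af * mepc_gp``
    spread over the combined OAO prevalence ``p``:
    ``(1 - af) * mepc_gp + af * mepc_gp / p``. The prevalence-weighted
    mean of the result is exactly ``mepc_gp``.
    """
    if not 0.0 <= af < 1.0:
        raise DomainError(f"attributable fraction must be in [0,1), got {af}")
    if mepc_gp < 0:
        raise DomainError(f"MEPC must be >= 0, got {mepc_gp}")
    p = sum(prevalence[k] for k in oao_set)
    if af > 0.0 and p <= 0.0:
        raise DomainError(
            "attributable fraction > 0 with zero OAO prevalence: "
            "no exposed population to carry the attributable cost"
        )
    base = (1.0 - af) * mepc_gp
    per_cat = {}
    for k in CATEGORIES:
        if k in oao_set and p > 0.0:
            per_cat[k] = base + af * mepc_gp / p
        else:
            per_cat[k] = base if af > 0.0 else mepc_gp
    return HealthCostProfile(mepc_by_category=per_cat, mepc_gp=mepc_gp)


def derive_case_distribution(
    prevalence: Mapping[BMICategory, float],
    rr: Mapping[BMICategory, float],
) -> dict[BMICategory, float]:
    """Proportion of deaths per category implied by prevalence and RR.

    pd_k = X_k RR_k / Sum_l X_l RR_l — the standard case-distribution
    construction when the death split is not observed directly.
    """
    weights = {k: prevalence[k] * rr.get(k, 1.0) for k in CATEGORIES}
    total = sum(weights.values())
    if total <= 0.0:
        raise DomainError("cannot derive case distribution: zero total weight")
    return {k: w / total for k, w in weights.items()}


def rockhill_paf(m: MortalityInputs) -> float:
    """Population attributable fraction: Sum_k pd_k (RR_k - 1)/RR_k.

    Equals 0 when every RR is 1; lies in (-inf, 1).
    """
    total_pd = sum(m.pd.get(k, 0.0) for k in CATEGORIES)
    if abs(total_pd - 1.0) > 1e-9:
        raise DomainError(f"case distribution sums to {total_pd:.9f}, expected 1")
    paf = 0.0
    for k in CATEGORIES:
        pd_k = m.pd.get(k, 0.0)
        rr_k = m.rr.get(k, 1.0)
        if pd_k == 0.0:
            continue
        if rr_k <= 0.0:
            raise DomainError(
                f"relative risk for {k.value} must be > 0 when cases occur there"
            )
        paf += pd_k * (rr_k - 1.0) / rr_k
    return paf


def excess_deaths(
    paf: float | Mapping[tuple[int, int, Sex], float],
    life_tables: Mapping[Sex, LifeTable],
    strata: Sequence[PopulationStratum],
) -> dict[tuple[int, int, Sex], float]:
    """Annual OAO-attributable deaths per stratum.

    Total deaths in a stratum are ``count`` times the band-averaged
    single-year death probability from the matching life table; the PAF
    (a scalar, or a per-stratum mapping when relative risks vary by age,
    e.g. with an alternate elderly mortality source) gives the
    OAO-attributable share.
    """
    out: dict[tuple[int, int, Sex], float] = {}
    for s in strata:
        lt = life_tables.get(s.sex)
        if lt is None:
            raise DomainError(f"no life table for sex {s.sex.value}")
        try:
            qx = lt.band_qx(s.age_lo, s.age_hi)
        except DomainError as exc:
            raise DomainError(
                f"stratum [{s.age_lo},{s.age_hi},{s.sex.value}]: {exc}"
            ) from exc
        paf_s = paf[s.key] if isinstance(paf, Mapping) else float(paf)
        if paf_s >= 1.0:
            raise DomainError(f"PAF must be < 1, got {paf_s}")
        out[s.key] = paf_s * s.count * qx
    return out
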