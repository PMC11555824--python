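# Methods

## The model

`fiscalbod` estimates the fiscal burden of overweight and obesity (OAO)
from a government-accounts perspective with a prevalence-based,
BMI-stratified cohort comparison. The population is partitioned into
(age band, sex) strata, and within each stratum into four BMI
categories: underweight (BMI < 18.5), normal (18.5–<25), overweight
(25–<30) and obese (≥30). OAO is the union {overweight, obese}
(BMI ≥ 25, the Japanese categorization); a scenario restricts it to
{obese} (the WHO cut-off).

Two cohorts are evaluated on identical inputs:

* **control** — the observed population;
* **intervention** — the counterfactual in which the OAO share of every
  stratum is reassigned to the normal-weight category (counts conserved).

For each cohort, annual government flows are accumulated over strata
*i*, sexes *j* and BMI categories *k*:

1. **Employment.** The OAO group's full-time and part-time employment
   probabilities are the general-population probabilities shifted by an
   additive marginal effect β_emp (clamped to [0, 1]); the reference
   group keeps the baseline. Retired persons are removed from the
   employment-eligible pool first, so `P(FT) = p_ft (1 − p_ret)`.
2. **Welfare rates.** Sick-leave and early-retirement rates of the OAO
   group are the baseline rates multiplied by hazard ratios, clamped to
   [0, 1]. The retirement hazard ratio is an *early*-retirement effect:
   it applies only to strata below the statutory retirement age of 65.
3. **Income.** OAO income is baseline income scaled by (1 + β_inc),
   a relative wage effect.
4. **Total income.** Per category:
   `Y = N [ P(FT)((1 − p_sl) + p_sl·s)·y_ft + P(PT)·y_pt ]`
   where *s* is the sick-pay replacement rate (default 2/3). In the
   base case sick leave applies to full-time workers only; a scenario
   extends the same split to part-time workers.
5. **Direct tax** = tax wedge × total income (single multiplier; no
   progressive schedule).
6. **Indirect tax** = VAT × (disposable income + transfer income),
   with disposable income = (1 − wedge) × total income and transfer
   income = pension payments to retirees.
7. **Healthcare.** Population medical expenditure per capita (MEPC) is
   split across BMI categories with an OAO-attributable fraction AF:
   non-OAO categories cost (1 − AF)·MEPC, OAO categories additionally
   carry AF·MEPC/p_OAO, so the prevalence-weighted mean is exactly the
   input MEPC. The category profile is always anchored on the *control*
   prevalence; evaluating the intervention cohort against that profile
   removes the attributable cost rather than re-spreading it.
8. **Mortality.** The population attributable fraction uses the
   Rockhill form `PAF = Σ_k pd_k (RR_k − 1)/RR_k`, with the case
   distribution derived as `pd_k = X_k RR_k / Σ_l X_l RR_l` when not
   supplied directly. OAO-attributable deaths (PAF × stratum deaths)
   remove half a person-year each (mid-year convention) from the OAO
   group's labor and transfer flows; the adjustment is switchable and
   its fiscal role is deliberately conservative, since only the number
   of excess deaths — not their fiscal treatment — is identified.

The net fiscal effect of a cohort is
`net = direct tax + indirect tax − transfers − healthcare`, and the
**burden** is the control-minus-intervention difference, reported with
burden-positive signs: tax components as revenue forgone
(intervention − control) and spending components as excess outlays
(control − intervention). The total equals the sum of the four
components and also the difference in net flows — the decomposition
identity every report must satisfy.

### Prevalence-reduction curve

For a fraction f ∈ [0, 1], f of each OAO category's share is reassigned
to normal weight and the net-flow gain over the control cohort is
recorded. By construction the curve is 0 at f = 0 and equals the full
burden at f = 1.

### Projection

Year t regrows the inputs: the combined OAO share grows by the
sex-specific annual rate (default 1.47 %/yr men, 0.47 %/yr women),
drawn from the normal-weight share (clamped at zero, with a warning)
and preserving the overweight:obese ratio; wages grow at 2 %/yr.
MEPC and the pension benefit follow wage growth by default
(switchable) — with that choice the model is homogeneous of degree one
in monetary inputs, so with zero prevalence growth the burden scales
exactly by the wage factor. Population counts are held flat unless a
projections table (year, sex, age_lo, age_hi, count) is supplied. The
NPV discounts undiscounted per-year totals at 2 %/yr; year 0 is
undiscounted. The reported decade growth compares the horizon-year
total *discounted to the base year* with the base-year total, so it
isolates epidemiological growth from wage inflation (the two rates
offset exactly at the 2 %/2 % defaults).

### Lifetime cohort model

A per-person comparison of an OAO individual against a non-OAO peer of
the same starting age (default 49), with obesity status fixed for life.
Each year the arm accrues taxes (while working), pension (once retired)
and healthcare; flows are survival-weighted and discounted. The life
table anchors population mortality: with OAO prevalence p and
prevalence-weighted relative risk r̄ at an age, the split
`qx_ref = qx / (1 − p + p·r̄)`, `qx_oao = r̄ · qx_ref` reproduces the
table's qx on average. Both arms face the stratum's early-retirement
hazard from age 50 (the OAO arm's hazard scaled by its HR) and
statutory retirement at 65 — a symmetric schedule chosen so that null
modifiers give exactly zero lifetime burden; an asymmetric schedule
(statutory-only for the reference arm) would manufacture a spurious
burden from the retirement rule itself. Ages beyond the stratum table's
coverage reuse the nearest band's rates (labor rates there are
effectively zero).

## Parameters

| Parameter | Default | Units | Source/rationale |
|---|---|---|---|
| tax wedge | 0.327 | fraction of labor cost | published Japanese value |
| VAT rate | 0.10 | fraction | published Japanese rate |
| sick-pay replacement | 2/3 | fraction of salary | Japanese sickness-allowance rate |
| pension benefit | 790 000 | JPY/person/yr | ≈ full basic pension |
| discount rate | 0.02 | /yr | Japanese guidance |
| wage growth | 0.02 | /yr | reported year-on-year cash-earnings trend |
| OAO prevalence growth | 0.0147 / 0.0047 | /yr, men/women | published forecast-derived rates |
| β_employment | −0.035 | probability | synthetic calibration (see below) |
| β_income | −0.02 | relative | synthetic calibration |
| HR sick leave / retirement | 1.3 / 1.3 | — | synthetic calibration |
| RR mortality (under/over/obese) | 1.2 / 1.05 / 1.35 | — | synthetic calibration; alternate ≥65 map 1.35 / 1.0 / 1.25 |
| AF healthcare | 0.04 | fraction of spend | synthetic calibration |
| yen per USD | 143.58 | — | reporting conversion, overridable |
| base-case age range | 18–70 | years | working-age scope; scenarios use 18–65/75/104 |

## What the synthetic data emulates — and what it does not

The generator produces age-structured inputs with the qualitative shape
of Japanese national statistics: OAO prevalence rising logistically to
a midlife plateau with a higher male asymptote; hump-shaped employment
and income profiles winding down near 68; retirement stock switching on
through the early 60s; MEPC rising exponentially with age; Gompertz
mortality (log-linear qx). The fixed calibration
(`japan_like_fixture`) has a working-age (18–70) population of
≈ 7.7 × 10⁷ and overall OAO prevalence ≈ 0.24, and uses the published
fiscal constants verbatim. Effect sizes are *not* published inputs;
they were chosen once at literature-plausible magnitudes such that the
calibration reproduces the qualitative structure reported for this
class of model: component ordering direct tax ≫ healthcare ≫ indirect
tax > pensions, a tornado led by the employment modifier and the tax
wedge, and a lifetime age profile whose tax component shrinks (and
transfer share grows) with starting age.

Passing tests therefore demonstrate correctness of the *machinery*
(identities, conservation laws, orderings, oracle equivalence on hand
ledgers) — not agreement with Japanese headline statistics, whose
underlying survey tables are not redistributable. The fixture's burden
total (≈ ¥2.1 tn) should be read as "right order of magnitude", not as
a reproduction.

## Numerical choices

* All probabilities clamped to [0, 1] after adjustment; incomes floored
  at 0.
* Band-level qx is the unweighted mean of single-year qx.
* The MEPC conservation identity, burden decomposition identity and
  reduction-curve endpoints hold to float round-off (tested at 1e-9
  relative against gross-flow scale).
* CSV round-trips are exact to the last ulp (`repr` floats written,
  `float_precision="round_trip"` on read).
* Degenerate inputs: AF > 0 with zero OAO prevalence is a domain error
  (no exposed population to carry the cost); RR = 0 with cases in the
  category is a domain error; empty/zero-count strata contribute zero
  flows.
* One-way sensitivity default ranges are ±20 % of the base value; for
  hazard ratios and relative risks the *excess* (HR − 1, RR − 1) is
  varied so a null association stays null.

## Design choices on genuinely open points

* β_employment additive on the probability scale and applied to both
  full-time and part-time probabilities (the same marginal effect);
  β_income multiplicative. Both scales are what labor-economics
  probit/wage regressions report.
* The retirement HR is applied as an early-retirement effect only
  (< 65); the 65+ retirement stock is statutory and identical across
  groups.
* Excess deaths enter the annual model's flows (half-year convention)
  by default rather than only the projection's population updates; the
  switch `mortality_affects_flows` disables it.
* Sex-specific values are supported for the scalar modifiers
  (β, HR, AF) via per-sex config keys; mortality RR maps are global.
* Sex-filtered scenarios zero the excluded sex's counts instead of
  dropping strata, so outputs keep their shape and the two single-sex
  runs sum exactly to the pooled run.

## Known limitations

* No dynamic BMI transitions within a year and no switching in the
  lifetime model; the prevalence model is static per year.
* No presenteeism, informal-care or broader societal costs — the scope
  is strictly government accounts.
* A single tax wedge, not a progressive schedule.
* Population counts held flat over the projection unless a projections
  table is supplied, which understates growth driven by demographic
  change.
* The synthetic calibration supports structural and qualitative claims
  only; magnitudes depend on effect sizes that real applications must
  replace with study-specific estimates.
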