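# fiscalbod

A fiscal (government-accounts) burden-of-disease model for overweight
and obesity (OAO), built for health economists and policy analysts who
need the *public-finance* footprint of excess weight rather than a
conventional cost-of-illness figure.

The core is a BMI-stratified prevalence model: the population is split
into (age band, sex) strata and four BMI categories (underweight <18.5,
normal 18.5–<25, overweight 25–<30, obese ≥30 kg/m²; OAO = BMI ≥ 25).
Published effect modifiers — an employment marginal effect β_emp, an
income effect β_inc, sick-leave/early-retirement hazard ratios, per
category mortality relative risks, and an attributable fraction AF of
medical spend — perturb the OAO group's labor, welfare, healthcare and
mortality outcomes. Annual government flows

net = direct tax + indirect tax − pension transfers − healthcare

with direct tax = tax wedge × labor income and indirect tax = VAT ×
(disposable income + transfers), are computed for the observed
("control") cohort and for a counterfactual ("intervention") cohort in
which all OAO mass is reassigned to normal weight. The fiscal burden of
OAO is the difference, decomposed into direct-tax loss, indirect-tax
loss, excess pension spending and excess healthcare spending. Mortality
enters through the Rockhill population attributable fraction
PAF = Σₖ pdₖ (RRₖ − 1)/RRₖ combined with life tables. On top of the
single-year model sit a prevalence-reduction curve, a 10-year
projection (growing OAO prevalence, wage growth, discounting), a
per-person lifetime cohort model, one-way sensitivity analysis
(tornado) and a scenario battery (age ranges, BMI ≥ 30 definition,
alternate elderly mortality, sick-leave scope, single-sex runs).

Because the underlying national survey and fiscal tables are not
redistributable, the package ships a synthetic-data module that
generates complete, validated input sets with the right qualitative
structure, plus one fixed Japan-like calibration. See
`docs/methods.md` for the model, its assumptions and what the
synthetic calibration does and does not support.

## Worked example

```sh
fiscalbod synth --out inputs/          # fixed Japan-like calibration
fiscalbod run --inputs inputs/ --out results/
```

prints

```
total burden: 2085.65 billion JPY
```

and writes `results/burden.csv`:

```
item,billion_jpy,billion_usd
Direct tax losses from employment,1051.42,7.32
Indirect tax losses (from employment income and transfers),206.98,1.44
Retirement payments,94.19,0.66
Healthcare costs,733.07,5.11
Total fiscal burden of OAO,2085.65,14.53
```

Reading: on the synthetic calibration (working-age population ≈ 77 M,
OAO prevalence ≈ 0.24), OAO costs the government ≈ ¥2.09 tn per year,
mostly forgone direct tax (lower employment and wages among the ~19 M
people with BMI ≥ 25) and OAO-attributable healthcare, with a smaller
excess in early-retirement pensions. The total row is exactly the sum
of the four components. The same inputs drive the other subcommands:

```sh
fiscalbod project   --inputs inputs/ --out results/   # 10-year series + NPV
fiscalbod curve     --inputs inputs/ --out results/   # gain per prevalence cut
fiscalbod owsa      --inputs inputs/ --out results/   # tornado table
fiscalbod scenarios --inputs inputs/ --out results/   # scenario battery
fiscalbod lifetime  --inputs inputs/ --age 49         # per-person model
```

The lifetime command reports, e.g.

```
start age 49: tax loss 1,428,695 JPY, transfer excess 1,019,967 JPY, total 2,448,662 JPY per person
```

the present value of the lifetime fiscal gap between an average-mix
49-year-old with OAO and a non-OAO peer.

`fiscalbod synth --seed N` generates a randomized input set instead of
the fixed calibration; every generated set passes the full input
validation.

### Output schemas

* `burden.csv` — item, billion_jpy, billion_usd (five rows).
* `scenarios.csv` — name, tax_revenue_loss, transfer_spending,
  net_fiscal_effect (JPY; net = tax + transfer for every row).
* `tornado.csv` — parameter, low, high, burden_low, burden_high, width,
  sorted by width with a leading base row.
* `curve.csv` — fraction, net_gain (JPY).
* `projection.csv` — year, four components, total, discounted_total.
* `report.json` — machine-readable summary plus metadata (config hash,
  seed) sufficient to rerun bit-identically.

Input formats (CSV column lists and the `[fiscal]/[modifiers]/[run]`
config sections) are documented in `fiscalbod/model_inputs.py`; the
`synth` command emits examples of all three files.

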