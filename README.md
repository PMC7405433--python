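# icucausal

Causal analysis of the "obesity paradox" in critically ill patients:
does obesity *cause* the lower in-hospital mortality observed among obese
ICU patients, or is the association an artifact of confounding, missing
data, and selection?

The package estimates the **average treatment effect in the untreated
(ATU)**,

ψ = E[Y(1) − Y(0) | A = 0],

the change in in-hospital mortality that non-obese patients (A = 0,
obesity defined as BMI ≥ 30 kg/m²) would have experienced had they been
obese, adjusting for 14 baseline confounders. Two arms are implemented
and compared end to end:

| arm | missing data | outcome/exposure models | estimator |
|---|---|---|---|
| traditional | complete-case | main-effects logistic regression | G-computation (direct standardization) with delta-method CI |
| robust | MICE (m = 50, Rubin's rules) | super learner (15 candidates, stratified 10-fold CV, L2/log/rank metalearners) | one-step TMLE with influence-curve SE and propensity truncation at [0.025, 0.975] |

Because no patient-level ICU dataset can be shipped, a first-class
synthetic-cohort generator (`icucausal.simulate`) reproduces the
statistical structure of a severity-selected ICU cohort — 18.9% obesity
prevalence, 14.4% in-hospital mortality, confounded exposure, ~2.7% of
exposure/confounder cells missing at random clustering into ~26.8%
incomplete rows — with a **known true ATU of −1.0 percentage points**, so
every stage of both arms is testable against ground truth. See
`docs/methods.md` for the models, calibration, and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (seed 2020) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_traditional_arm.py
python analysis/03_robust_arm.py          # add --paper for m=50 + 15 candidates
python analysis/04_sensitivity_cutoffs.py
```

Output of steps 1–3:

```
cohort n = 6557
obesity prevalence (exposure known): 18.6%
in-hospital mortality: 14.1%
ICU mortality: 9.5%
incomplete rows: 27.1%
missing cells: 2.7%
true ATU: -1.00% (MC SE 0.000)

complete cases: 4780 of 6557 (27.1% discarded)
adjusted obesity OR: 0.85 (0.68-1.07), P = 0.173
raw RD (complete A): -1.02% (-3.20 to 1.15)
raw RD (complete A,C): -1.32%
traditional ATU: -1.68% (-4.02 to 0.65), P = 0.158
missingness exposed vs unexposed: 24.0% vs 22.8%, P = 0.349

imputations: m = 5 (iterations 5)
robust ATU: -0.94% (-3.17 to 1.30), P = 0.410
within-imputation var: 1.151e-04; between: 1.154e-05; total: 1.289e-04
propensity truncation: 0.0% of patients on average
```

Reading: the generator's true effect is −1.00%. The raw risk
difference (−1.02%) happens to sit near it; the complete-case
G-computation estimate (−1.68%) drifts away — complete-case restriction
under outcome-dependent missingness plus finite-sample confounding
adjustment error — while the robust arm (−0.94%) lands on the truth with
an honest interval. On a single cohort of this size all three carry
sampling SEs near ±1.2 points; the coverage and double-robustness
simulations in `tests/test_acceptance.py` are the systematic version of
this comparison.

The same pipeline is scriptable on any cohort CSV in the package's
column dialect via the CLI:

```bash
icucausal simulate --n 6557 --seed 7 --out cohort.csv
icucausal analyze --cohort cohort.csv --profile test --arm both --outdir results/
icucausal sensitivity --cohort cohort.csv --profile test --cutoffs 25,30,35
```

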