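# Methods

## The estimand

The package estimates the **average treatment effect in the untreated
(ATU)** of obesity on in-hospital death in an ICU cohort,

ψ = E[Y(1) − Y(0) | A = 0],

the marginal causal risk difference that non-obese patients would have
experienced had they been obese. A = 1{BMI ≥ 30 kg/m²} is the exposure,
Y in-hospital death, and C a set of 14 baseline confounders (age, sex,
ethnicity, income, smoking, alcohol, physical activity, hypothyroidism,
chronic glucocorticoid therapy, solid and hematologic malignancy,
dementia, HIV/AIDS, calendar time). The untreated subgroup is targeted
because non-obese ICU patients would plausibly have been admitted (and
severity-selected) regardless of their obesity status, making the ATU
less exposed to collider-stratification bias than the ATT or ATE.

Two arms produce an estimate:

* **Traditional arm** — complete-case main-effects logistic regression of
  Y on A and C, followed by direct standardization (G-computation): each
  record's risk is predicted under A:=1 and A:=0 and both predictions are
  averaged over the observed A = 0 subgroup. The CI uses the delta
  method over the coefficient covariance (gradient of the
  standardization functional); a nonparametric bootstrap is available as
  a config option (`se_method="bootstrap"`). How the interval should be
  computed is genuinely open for this estimator; the delta method is the
  default because it is deterministic and was verified against the
  bootstrap to within 15% relative on synthetic cohorts.
* **Robust arm** — multiple imputation by chained equations (MICE), then,
  on each completed dataset, super-learner fits of the outcome mechanism
  Q(A,W) = P(Y=1|A,W) and the exposure mechanism g(W) = P(A=1|W), a
  one-step TMLE targeting ψ, and Rubin's-rules pooling of the m
  (estimate, variance) pairs.

## One-step TMLE for the ATU

With initial fits Q̂(0,W), Q̂(1,W) and truncated ĝ(W), a single logistic
fluctuation with offset logit Q̂ and two intercept-free clever covariates

H₁(A,W) = A·(1 − ĝ)/(ĝ·π̂₀),  H₀(A,W) = −(1 − A)/π̂₀,  π̂₀ = mean(1 − A),

is fitted by maximum likelihood, updating the two counterfactual
surfaces separately (ε₁, ε₀). The plug-in ψ̂ = mean over A = 0 of
[Q̂\*(1,W) − Q̂\*(0,W)] then solves the efficient-influence-function
estimating equation exactly:

D = (H₁ + H₀)(Y − Q̂\*(A,W)) + (1−A)/π̂₀ · (Q̂\*(1,W) − Q̂\*(0,W) − ψ̂),
mean(D) = 0,

which the implementation asserts to 1e−8 on every run. The standard
error is sd(D)/√n (influence curve), and Wald intervals use
z₀.₉₇₅ = 1.959964. Two structural cross-checks are built into the test
suite: ψ̂ equals the nonparametric stratified estimator exactly when the
nuisances are saturated on a discrete confounder (targeting is a no-op at
the NPMLE), and the independent ATT implementation applied to the
recoded exposure (A′ = 1 − A, surfaces and propensity swapped) reproduces
−ψ̂ to 1e−10.

Propensity truncation uses **fixed bounds [0.025, 0.975]** (the standard
gbound convention), not empirical percentiles of the weight
distribution: the per-patient truncation fractions the pipeline reports
are only meaningful under fixed bounds. "One-step" means a single
logistic fluctuation, which suffices to solve the EIF equation for this
estimand; no universal-least-favorable-submodel iteration is performed.
The influence-curve SE is the within-imputation variance; all
between-imputation uncertainty is carried by Rubin's B.

## Super learner

Stacking with stratified K-fold cross-validation (default K = 10, one
fold partition per mechanism per dataset, shared by all candidates).
Convex weights over the candidate library minimize the empirical risk of
the weighted prediction under one of three losses: squared error (L2),
log loss (clipped at 1e−6), or rank loss = 1 − AUC with midrank tie
correction. L2 and log are convex over the simplex and solved with
SLSQP; rank loss is non-convex and uses 20 seeded multi-starts with the
L2 solution as one start. After optimization the best single candidate
is a guaranteed fallback, so the ensemble's CV risk never exceeds the
best vertex's for the optimized loss. A candidate that fails on a
training split has its out-of-fold cells filled with the training-fold
outcome mean, is flagged, and is excluded from the weight support.

The full library has 15 candidates: the null estimator (unconditional
mean), main-effects logistic regression, bidirectional-AIC stepwise
logistic regression (a *prediction* algorithm inside CV — the
traditional arm itself never drops covariates), five elastic-net
logistic regressions with mixing parameter 0, 0.25, 0.5, 0.75, 1,
random forest, extreme gradient boosting (xgboost), an RBF support
vector machine with Platt-scaled probabilities, an additive tree
ensemble (depth-2 gradient-boosted trees), and additive polynomial
logistic models of degree 2, 3 and 4 on the continuous features.
Hyperparameters are fixed defaults recorded in `learners.py`; no
automatic tuning is performed. A reduced four-candidate library (null,
main-effects logistic, ridge, gradient boosting) drives the test suite
and the scaled-down pipelines. "Rank loss" is read as 1 − AUC, the
standard interpretation for binary outcomes. The default operating loss
for the targeting step is the log loss.

## Multiple imputation

Fully conditional specification with, per variable type: predictive mean
matching with 5 donors and a Bayesian coefficient draw (continuous),
Bayesian logistic draws (binary), and multinomial-logistic category
draws (unordered categoricals; the category probabilities are not
parameter-drawn, a mild departure from fully proper imputation that has
negligible effect at these missingness rates). Missing cells are
initialized by marginal draws; variables are visited in descending
missingness order (ties alphabetical) for `n_iter` = 10 cycles; m = 50
imputations by default. Every conditional model includes the outcome
and all other analysis variables as predictors. BMI is imputed directly
as a variable and the obesity indicator re-derived as 1{BMI ≥ cutoff},
preserving the deterministic exposure–BMI link (height and weight are
left missing in completed datasets; they feed no model). A conditional
model that fails (e.g., an empty category) falls back to a marginal draw
with a logged warning.

Pooling follows Rubin's rules: T = W̄ + (1 + 1/m)·B, with a t reference
using the Barnard–Rubin adjusted degrees of freedom when the
complete-data df is supplied (at m = 50 and n ≈ 6557 the difference from
the normal reference is negligible; B = 0 falls back to the normal).

## Synthetic cohort generator

No patient-level data are distributable, so the generator is a
first-class module that emulates the statistical structure of a
severity-selected (SAPS II ≥ 32) adult ICU cohort:

* **Confounders** are drawn independently from marginals matched to
  published baseline tables (age: truncated N(64.1, 15.3²) on [16, 100];
  income: truncated N(25.9, 4.1²) k€/yr; calendar time uniform on
  [0.2, 3.2] years; categorical and binary fields at their observed
  nonmissing frequencies). Independence is a deliberate simplification —
  only marginals are recoverable from published tables; an analysis of
  real data would face correlated confounders. A Gaussian-copula
  correlation hook was considered and deferred (nothing in the test
  suite needs it; the estimators never assume independence).
* **Exposure**: A ~ Bernoulli(expit(α₀ + αᵀW)) with coefficients chosen
  to reproduce the qualitative obese-vs-non-obese baseline contrasts and
  α₀ calibrated by large-n Monte-Carlo root finding so that prevalence
  is 18.9%. BMI is then drawn consistently with A (truncated normal
  below the cutoff; 30 + lognormal above), so re-deriving obesity from
  BMI reproduces A.
* **Outcome**: counterfactual pair (Y(0), Y(1)) from a main-effects
  logistic model whose confounder coefficients are realistic adjusted
  log-odds ratios for ICU in-hospital mortality; the observed Y = Y(A)
  by construction (counterfactual consistency is asserted in tests).
  The intercept is calibrated to 14.4% marginal mortality and the
  exposure coefficient (−0.0868) to a true ATU of −0.010 — a small
  protective effect on the same scale as the raw associations the
  analysis investigates. A shared uniform couples Y(0) and Y(1)
  (monotone coupling); only the marginal laws matter for any estimand
  used.
* **Missingness** (MAR): the outcome is never masked. Per-variable base
  rates come from the published per-variable missing fractions; each
  record belongs to a low- or high-missingness documentation class whose
  probability depends on the (always observed) outcome and age, and
  cells are masked independently within class at base_rate × κ_class.
  The class structure exists because the two published facts — ≈2.7% of
  cells missing and only ≈26.8% of rows incomplete — are jointly
  impossible under independent cell masking (2.7% i.i.d. over 15 fields
  gives ≈33.7% incomplete rows); positive within-row clustering is the
  only mechanism that satisfies both, and (γ₀, κ_lo, κ_hi) =
  (−1.953, 0.674, 6.455) were calibrated once to hit both targets.
* **Scenario presets**: `default` (protective effect, MAR missingness),
  `complete` (no missingness), `null` (zero effect, for coverage
  studies), `harmful`, and `misspecified` (strong age–exposure
  confounding, α_age = 0.9, plus an omitted quadratic-age outcome term,
  β_age² = 0.55, so that a main-effects outcome model is materially
  biased — the double-robustness contrast scenario).
* Random streams are split per purpose (confounders / exposure / outcome
  / anthropometrics / masking) via `SeedSequence.spawn`, so changing one
  scenario leg leaves the others bitwise identical.

`true_atu` evaluates ψ by Monte Carlo in Rao-Blackwellized form
(averaging P[Y(1)=1|W] − P[Y(0)=1|W] over simulated A = 0 individuals,
default 10⁶ draws), and reports the MC standard error alongside.

**What passing tests do and do not show.** The generator has independent
confounders, a correctly parameterized logistic outcome (except in the
misspecification scenario), exact MAR, and no measurement error in BMI
beyond the implausibility rule. Validity results on it demonstrate that
the estimators are implemented correctly and achieve nominal behavior
when their assumptions hold — not that those assumptions hold in any
real ICU cohort (unmeasured confounding, MNAR missingness, estimated
heights/weights, and collider selection remain exactly as open on real
data as they ever were).

## Cohort model

BMI = weight/height² is treated as missing when either input is missing
or the result is outside [10, 80] kg/m² (biologically implausible,
attributed to input error); obesity is missing exactly when BMI is.
The exclusion cascade runs in a fixed order — weight-related admission
reason, repeat admissions (first admission kept; ties on admission time
broken by identifier), SAPS II < 32, SAPS II missing — and the
provenance log records order-dependent per-stage counts that always
telescope. Quartiles use the linear-interpolation (type-7) convention.
Baseline tables report percentages of the group size including an
explicit Missing level, to one decimal; estimates are displayed to two
decimals. Missing values are the pandas NA sentinel of the column's
dtype throughout; CSVs encode missing as an empty field with a JSON
provenance sidecar.

Z-standardization constants for age, income and calendar time are
computed on the analysis sample actually fed to each model (complete
cases, or each imputed dataset) and logged; the same convention is used
for all three variables.

## Numerical choices

* Logistic MLE via statsmodels GLM/IRLS, 100-iteration cap, score-norm
  check; observed-information covariance. Non-convergence or separation
  raises with diagnostics rather than returning silently.
* Fluctuation ε fitted by GLM with offset, tolerance 1e−12.
* Probabilities clipped to [1e−6, 1 − 1e−6] before logit transforms and
  inside the log loss.
* Simplex optimization: SLSQP, ftol 1e−12 (convex losses), projected
  back to the simplex; best-vertex fallback guarantees dominance.
* z₀.₉₇₅ = 1.959964 internally; display rounding is presentation-only.
* Degenerate inputs: empty estimand subgroups, all-one-class outcomes,
  zero group sizes and invalid truncation bounds raise typed errors
  (ConfigError / DataError), which the CLI maps to exit codes 2 / 3.

## Problem sizes

Defaults match the study conditions (n = 6557, m = 50, K = 10, 15
candidates, truncation [0.025, 0.975]). The simulation suites in the
tests and the acceptance script use scaled sizes chosen as standard
desk-scale study designs: coverage at n = 4000 over 100 replicates;
double-robustness at n = 8000 over 10 seeds; super-learner concentration
at n ∈ {500, 2000, 8000} over 10 seeds with the reduced library;
the robust arm in the acceptance script runs m = 5 imputations with the
reduced library at K = 10. `analysis/03_robust_arm.py --paper` runs the
full m = 50 / 15-candidate configuration.

## Known limitations

* Independent confounders and a logistic outcome law make the default
  synthetic world easier than real data for every estimator; the
  misspecification scenario probes only one direction of model error.
* The multinomial imputation draw is not fully proper (no parameter
  draw); Rubin variances may be very slightly understated for
  categorical-driven functionals.
* The bootstrap SE option refits the outcome model only (not the
  exclusion cascade or imputation).
* Nested-CV performance tables are computed on request, not in the
  default pipeline run.
* No cross-fitted (CV-)TMLE, no collaborative TMLE, no continuous-dose
  exposure model, and no MNAR sensitivity analysis (MAR is assumed
  throughout, as in the analysis this package operationalizes).
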