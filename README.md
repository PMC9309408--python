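# accept2

Individualized prediction of chronic obstructive pulmonary disease (COPD)
exacerbations: how many a patient will have over the next year, how likely
any of them are to be severe, and whether acting on those predictions beats
simple history-based rules.

## The problem

Preventive COPD therapies are typically triggered by the guideline
"frequent exacerbator" criterion: at least two moderate or at least one
severe exacerbation in the previous year.  That rule throws away most of
what is known about a patient.  A risk model can use demographics, lung
function, symptom burden, and medication history to produce an
individualized exacerbation rate and severity — but a model developed in
one population is usually miscalibrated in another, so it must be
recalibrated against local data and re-validated before its predictions can
inform treatment decisions.

This package implements that entire workflow:

* **`model_core`** — the joint rate-severity model.  Patient-level
  exacerbations follow a Poisson process with rate
  `λ = exp(β'x + z₁)`; each exacerbation is severe with probability
  `p = expit(γ'x + z₂)`, where `(z₁, z₂)` are correlated Gaussian random
  effects (σ₁, σ₂, ρ) capturing between-patient heterogeneity beyond the
  covariates.  Closed marginal quantities (probability of any exacerbation,
  of a severe one, of meeting the frequent-exacerbator pattern) are
  obtained by 2-D Gauss–Hermite quadrature, and the model can be refit to a
  cohort by marginal maximum likelihood with reported standard errors.
* **`recalibration`** — 3-knot natural cubic spline maps from predicted to
  observed event rates (fitted as Poisson regressions with a log follow-up
  offset), with separate maps for all and severe exacerbations and a
  reconciliation step that keeps severe ≤ all.
* **`validation`** — decile calibration tables with exact Poisson
  (Garwood) intervals, calibration-in-the-large, the integrated calibration
  index (ICI), a model-based ROC (mROC) calibration test, and
  inverse-probability-of-censoring-weighted time-dependent AUC with
  bootstrap comparisons.
* **`decision_analysis`** — net benefit, decision curves against
  treat-all / treat-none / history-based strategies, and interventions
  avoided per 100 patients.
* **`imputation`** — multiple imputation for predictors that are partially
  or wholly missing in a validation cohort, with prediction pooling.
* **`synthetic`** — generative cohorts with the statistical structure the
  tool assumes, including ready-made profiles matching an
  observational-study population (1.20 moderate/severe and 0.27 severe
  events per person-year) and a trial placebo arm (1.02 and 0.18), used
  throughout the tests.
* **`io` / CLI** — CSV cohort formats, JSON coefficient and recalibration
  files, and an `accept2` command with `simulate`, `predict`,
  `recalibrate`, `validate`, and `dca` subcommands.

## Worked example

Score a single high-risk patient with the demonstration coefficient set
(calibrated against the observational-profile population):

```python
from accept2 import synthetic
from accept2.model_core import outcome_probabilities
from accept2.types import CovariateVector

coef = synthetic.eclipse_like(n=2000, seed=0).true_coefficients

patient = CovariateVector(
    n_moderate_prior=2, n_severe_prior=1, age=67.0, sex=1, smoker=0,
    fev1_pct_pred=38.0, sgrq=58.0, bmi=24.0, oxygen=0, statin=0,
    lama=1, laba=1, ics=1,
)
pred = outcome_probabilities(patient, coef, horizon=1.0)
print(f"expected exacerbations / year      : {pred.rate_all:.2f}")
print(f"expected severe exacerbations / yr : {pred.rate_severe:.2f}")
print(f"P(any exacerbation within 1 y)     : {pred.p_any:.3f}")
print(f"P(>=2 moderate or >=1 severe)      : {pred.p_primary:.3f}")
print(f"P(any severe within 1 y)           : {pred.p_any_severe:.3f}")
```

Output:

```
expected exacerbations / year      : 2.56
expected severe exacerbations / yr : 0.88
P(any exacerbation within 1 y)     : 0.802
P(>=2 moderate or >=1 severe)      : 0.641
P(any severe within 1 y)           : 0.476
```

The same workflow from the command line, on a synthetic cohort:

```bash
accept2 simulate --seed 7 -n 1000 --profile eclipse_like --out demo
accept2 predict  --cohort demo/cohort.csv --events demo/events.csv \
                 --coefficients demo/true_coefficients.json --seed 7 --out demo
accept2 validate --cohort demo/cohort.csv --events demo/events.csv --seed 7 --out demo
accept2 dca      --cohort demo/cohort.csv --events demo/events.csv --seed 7 --out demo
```

`demo/metrics.json` from this run (879 patients retained after the
short-follow-up exclusion):

```
auc                     0.706   (95% CI 0.671-0.745)
calibration_in_the_large  0.191
ici_rate                  0.193
ici_risk                  0.038
mroc_test p               0.036
```

The positive calibration-in-the-large and the rejected mROC test show the
raw score over-predicts on this cohort — prior-year counts realized under
the frailty process are a heavier-tailed predictor than the covariates the
score was built on — which is exactly the situation the `recalibrate`
subcommand repairs (see `docs/methods.md`).

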