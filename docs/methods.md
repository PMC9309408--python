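# Methods

## Joint rate–severity model

For patient *i* with covariate vector *x*, exacerbations arrive as a
homogeneous Poisson process with annual rate

    λᵢ = exp(β'xᵢ + z₁ᵢ),

and each exacerbation is independently severe with probability

    pᵢ = expit(γ'xᵢ + z₂ᵢ),

where (z₁ᵢ, z₂ᵢ) ~ N₂(0, Σ), Σ having standard deviations σ₁ and σ₂ and
correlation ρ.  The random effects capture between-patient heterogeneity
in exacerbation frequency and severity not explained by the covariates and
induce overdispersion relative to Poisson counts.

Marginal (population-averaged) quantities over a horizon *t* are
expectations over the random effects:

* expected count: `E[tλ] = t·exp(β'x + σ₁²/2)` (closed form);
* probability of ≥1 exacerbation: `1 − E[exp(−tλ)]`;
* probability of ≥1 severe exacerbation: `1 − E[exp(−tλp)]`
  (severe events are a Poisson thinning with retention *p*);
* probability of the "frequent exacerbator" pattern (≥2 moderate or
  ≥1 severe): `1 − E[exp(−tλ)·(1 + tλ(1−p))]`.

The two-dimensional expectations are evaluated by a product Gauss–Hermite
rule (32 nodes per dimension by default) after a Cholesky transform of Σ;
at σ₁ = σ₂ = 0 the results coincide with the Poisson closed forms to
1e-8, and across parameter space they agree with event-level Monte-Carlo
simulation within Monte-Carlo error (both are enforced by tests).

### Estimation

`fit_joint_model` maximizes the marginal likelihood.  For patient *i* with
nᵢ total and kᵢ severe events in follow-up tᵢ, the contribution is

    ∫∫ Poisson(nᵢ; tᵢλᵢ(z₁)) · C(nᵢ,kᵢ) pᵢ(z₂)^kᵢ (1−pᵢ(z₂))^(nᵢ−kᵢ) φ₂(z) dz,

evaluated on a 9-node product Gauss–Hermite grid with a log-sum-exp
reduction.  Optimization is L-BFGS-B on the unconstrained parameterization
(log σ₁, log σ₂, atanh ρ), starting from moment fits that ignore the
frailty, with optional jittered multi-starts.  The objective is the *mean*
per-patient negative log-likelihood: with the summed objective the first
projected gradient step of L-BFGS-B jumps to a corner of the box and the
line search stalls, a failure mode we observed directly.  Standard errors
come from a central-difference Hessian of the summed objective with a
delta-method transform back to (σ₁, σ₂, ρ).  A simulation test verifies
that every parameter is covered by ±3 reported standard errors in ≥90% of
replicates at n = 2000.

## Recalibration

Predicted rates are recalibrated against observed counts with a natural
cubic spline with three knots at the 10th/50th/90th percentiles of the log
predicted rate, i.e. a Poisson regression

    log E[count] = c₀ + c₁·B₁(log r̂) + c₂·B₂(log r̂) + log(follow-up),

using the truncated-power natural-spline basis (linear beyond the boundary
knots, C² at the knots).  Only three knots are used to avoid overfitting;
there is no cross-validated tuning.  Separate maps are fitted for all and
for severe exacerbations.  When both maps are applied to a prediction, the
recalibrated severe rate is capped at the recalibrated all rate, the
severity probability is re-derived as their ratio, and the pattern
probabilities are recomputed from linear predictors solved back from the
recalibrated marginals.  This reconciliation makes the identity map an
exact no-op only when ρ = 0; with ρ ≠ 0 the re-solved predictors absorb a
small (second-order) discrepancy, which we accept in exchange for
guaranteed internal consistency (severe ≤ all, pattern probabilities
coherent).  A cohort with no observed events yields a degenerate map that
sends every prediction to effectively zero.

## Validation metrics

* **Decile calibration**: patients are split into ten equal groups by
  predicted value; observed rates carry exact Poisson (Garwood) intervals,
  observed risks Clopper–Pearson intervals.
* **Calibration-in-the-large**: mean predicted rate minus total observed
  events over total person-time.
* **ICI**: mean absolute difference between predictions and a locally
  weighted (lowess, frac = 0.75, zero robustness iterations) smooth of the
  observed outcome against the prediction.  For rates, the smooth is of
  count/follow-up against predicted rate.
* **mROC test**: the model-based ROC is the curve the empirical ROC should
  follow if predictions are calibrated; the test statistic combines
  calibration-in-the-large with the supremum distance between the
  empirical and model-based curves, each standardized by its null-sample
  moments, with the null distribution generated by Bernoulli draws from
  the predictions themselves (an exchangeable parametric bootstrap; the
  reported p-value is (1 + #{null ≥ observed})/(B + 1)).  Its type-I error
  at α = 0.05, verified over 1000 calibrated replicates, is 0.049.
* **Time-dependent AUC**: cumulative-case/dynamic-control AUC at a
  landmark, with inverse-probability-of-censoring weights from the
  Kaplan–Meier estimator of the censoring distribution (via lifelines).
  Subjects observed event-free through exactly the landmark count as
  controls.  Without censoring before the landmark the estimator reduces
  exactly to the Mann–Whitney statistic (enforced by a test).  Confidence
  intervals and model comparisons use patient-level (paired) bootstrap.

## Decision analysis

Net benefit at threshold p_t is TP/n − FP/n · p_t/(1−p_t).  Decision
curves always include treat-all and treat-none references; binary
strategies (e.g. the guideline history rule) enter as 0/1 prediction
vectors.  Interventions avoided per 100 patients at equal sensitivity is
ΔNB·(1−p_t)/p_t·100.

## Synthetic cohorts

Covariates are drawn independently from truncated-normal, Bernoulli, and
Poisson marginals; two profiles match the populations the workflow is
designed around (an observational cohort: mean age 63.3, 65.2% male, 1.20
all and 0.27 severe events per person-year; a trial placebo arm: 65.5,
77.2%, 1.02 and 0.18, with the medication indicator wholly missing and the
symptom score missing for 24%).  Rate and severity intercepts are
calibrated numerically against the target population rates (exact log
shift for the all-event rate; one-dimensional root finding for the severe
rate).  Exacerbations are generated by running the joint model forward
over a two-year horizon: year one supplies the prior-event predictors,
year two the outcomes, and patients with under 0.3 years of outcome
follow-up are excluded (≈13% in the observational profile, ≈28% in the
trial profile, produced by an exponential-dropout mixture).  Realized
year-one counts are capped at 10 moderate / 5 severe before being used as
predictors: the scoring model is log-linear in history counts, so the
frailty's heavy tail would otherwise produce unboundedly large predicted
rates, whereas real risk scores only accept history inputs over a bounded
clinically plausible range.

The miscalibration scenario divides the generating event rate of
prior-year non-exacerbators by a chosen factor while the scoring model
keeps the original coefficients, reproducing a model that over-predicts in
low-risk patients; tests verify that spline recalibration restores
low-decile observed/predicted ratios to within ±15%.

Because generation conditions on baseline covariates but scoring uses
realized year-one counts, the raw score is genuinely (mildly)
miscalibrated on these cohorts even when scored with the generating
coefficient set — a deliberate feature mirroring the transportability
problem the recalibration layer exists to fix.

## Numerical choices and limitations

* Gauss–Hermite quadrature (32 nodes scoring, 9 fitting) trades accuracy
  against runtime; agreement with Monte-Carlo oracles is enforced at both
  settings.
* The severity model assumes conditional independence of severities given
  z₂; within-patient severity clustering beyond the random effect is not
  modeled.
* The censoring-weight estimator assumes censoring independent of the
  marker; informative dropout would bias the time-dependent AUC.
* Multiple imputation draws from single-variable conditional models
  (logistic or Gaussian) rather than chained equations; adequate for one
  or two incomplete predictors, not for general missingness patterns.
* Imputation pooling averages predictions rather than coefficients, which
  is the appropriate combination when the prediction model itself is fixed.
* Synthetic profiles are software test fixtures matching headline margins
  of the motivating populations; they are not reconstructions of any real
  cohort.
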