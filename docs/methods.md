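# Methods

This note documents the statistical procedures implemented in `miselect`,
the numerical choices behind them, and what the synthetic-data experiments
do and do not establish.

## Data-generating mechanisms

Both mechanisms draw latent covariates from a multivariate normal
distribution with mean 0, unit variances, and a fixed correlation matrix,
then dichotomize a fixed subset at 0 into {0, 1} indicators.

**Mechanism one** (p = 15): all correlations zero except
ρ(1,10) = ρ(2,6) = ρ(7,14) = ρ(9,13) = 0.5, ρ(4,8) = −0.7, ρ(7,8) = 0.3,
ρ(11,12) = 0.7 (checked positive definite at construction; smallest
eigenvalue ≈ 0.20).  Covariates x2, x4, x5, x9, x10, x11, x12 are
dichotomized.  The outcome is Bernoulli with

```
logit P(Y=1 | X) = −0.25 − 0.5·x4 + 0.5·(x5 + x6 + x7) + x8 + x9 + 1.5·x10
```

where the coefficients apply to the *transformed* covariates (binary
columns in {0, 1}).  x1–x3 and x11–x15 are noise.

**Mechanism two** (p = 25): AR(1) correlation ρ|i−j| with ρ = 0.5; the
first 15 covariates are typed and coefficiented as in mechanism one; x16 –
x25 are continuous noise.

A deliberate point of record: with these published constants the mean
linear predictor is −0.25 + 0.5·(−0.5 + 0.5 + 1 + 1.5) = 1.0, and the
empirical outcome prevalence is ≈ 66 % (mechanism one) and ≈ 64 %
(mechanism two) — not the ≈ 60 % sometimes quoted for this design.  No
alternative reading (outcome on the latent scale: ≈ 47 %; centered or ±1
binary coding: ≈ 46–47 %) reaches 60 %, so the package implements the
constants literally.  Downstream summaries that assume 60 % prevalence
(events-per-variable ≈ 10 at n = 400; complete-case percentage 65 at 10 %
missingness) are correspondingly shifted here (EPV ≈ 8.6; complete cases
≈ 63 %), and comparisons against such figures in the acceptance suite are
expected to fail for that reason alone.  See also "Limitations".

### Missingness (MAR)

For every variable j in the incomplete set J (mechanism one:
{2,5,7,8,12,14}; mechanism two: additionally {16,17,19,23}), the
missingness indicator is Bernoulli with a *shared* per-subject probability

```
logit P(R_ji = 1) = α₀ + 0.5 · Σ_{k∉J} X_ki + 0.5 · Y_i
```

— a function of fully observed quantities only, hence missing at random.
Binary covariates enter this sum in their {0, 1} coding.  Indicators are
drawn independently across j given p_i.  α₀ is re-solved for every
generated dataset by Brent's method on the monotone equation
mean_i expit(α₀ + offset_i) = miss, bracketed analytically and solved to
1e−10, so each incomplete variable is missing at rate `miss` on average
and the overall missing-entry fraction is |J|·miss/p.

## Chained-equations imputation

`impute(data, m, cycles=5, donors=5)` is a self-contained MICE
implementation.  Missing entries are initialized by random draws from the
observed values of their column; each of 5 sweeps (a conventional cycle
count; exposed as a parameter) visits incomplete variables in ascending
missingness order — stabilizing early sweeps — and re-imputes each from a
model on all other covariates plus the (always observed) outcome:

* **continuous** — predictive mean matching, type 1: a linear regression
  on observed cases with coefficients drawn from the
  normal-inverse-χ² approximation to their posterior; each missing case
  copies the observed value of one of the 5 donors nearest in predicted
  mean (point-estimate predictions for donors, perturbed-draw predictions
  for missing cases).  Imputed values are therefore always observed donor
  values.
* **binary** — logistic regression with a coefficient draw from
  N(β̂, Cov̂), then Bernoulli imputation from the implied probabilities.
  Separated sub-models fall back to a ridge-stabilized fit (logged);
  one-class targets are imputed as the constant class.

The outcome is never imputed.  Proper-imputation behavior is verified by
parameter recovery: pooled per-completion maximum-likelihood estimates of
the outcome model recover the true coefficients at n = 2000, m = 10 within
Monte-Carlo tolerance, with errors comparable to the complete-data MLE.

## Penalized logistic core

The lasso solver minimizes the weighted negative average log-likelihood
plus λ‖β‖₁ with an unpenalized intercept.  Observation weights are
normalized to mean 1; covariates are standardized internally to weighted
mean 0/variance 1 and coefficients returned on the original scale.  The
grid is 100 log-spaced values from λ_max (the smallest penalty that zeroes
every slope, computed in closed form) down to 0.001·λ_max, solved with
warm starts by IRLS + cyclic coordinate descent with soft thresholding,
active-set inner iterations and full sweeps to admit violators.
Convergence is declared when the largest coefficient change falls below
1e−7.  Every returned solution satisfies the KKT subgradient conditions to
1e−5 (property-tested on random weighted problems), the λ = 0 solution
matches the unpenalized MLE to 1e−4, and solutions are invariant (1e−6) to
row duplication with proportionally reduced weights — the identity that
makes the stacked-data analysis well defined.

Penalty choice is a single 10-fold cross validation on the binomial
deviance (held-out probabilities clipped at 1e−15; per-fold weighted mean
deviance, averaged over folds; se = sd/√k).  Folds are stratified by
outcome at the subject level — avoiding single-class folds at n = 200 —
and, on stacked data, assigned per subject so each subject's m rows are
held out together.  `lambda_opt` minimizes the mean curve (ties broken
toward the larger penalty); `lambda_1se` is the largest penalty within one
standard error *at the minimizer* (the standard convention).  With
identical fold assignments and the same grid, the whole CV curve and both
chosen penalties agree with R's `cv.glmnet` (tested via Rscript).

## Selection strategies

Implementation details that the method names leave open:

* **Inclusion frequencies** (BBeF, BLaF): B bootstrap resamples (subjects
  with replacement, size n) are drawn independently from each of the m
  completions; the base selector runs on each of the m·B samples, with the
  lasso penalty re-chosen by a fresh 10-fold CV per sample.  Fits that
  fail (separation in backward elimination, a single-class resample) are
  logged and excluded from the denominator.  The threshold comparison is
  *inclusive* (frequency ≥ 50 % selects).  The final model refits the
  selected set unpenalized on each completion and averages intercept and
  slopes (Rubin point-estimate pooling).  An empty selection yields an
  intercept-only model.
* **Backward elimination** uses AIC: from the full model, greedily remove
  the covariate whose removal most decreases AIC; stop when none does.
  Its implicit per-variable retention rate on pure noise is
  P(χ²₁ > 2) ≈ 0.157, which the tests recover empirically; the
  implementation reproduces `MASS::stepAIC` exactly on reference datasets.
* **SepAv/SepAvF** average the per-completion lasso coefficient vectors
  over *all* m completions — zeros from completions where a variable was
  inactive included — which is Rubin-consistent and reproduces SepAv's
  characteristic many-small-coefficients behavior.  SepAv keeps the union
  of active sets; SepAvF those active in ≥ 50 % of completions (a nested
  subset by construction).
* **Stack/StackW** use row weights 1/m (uniform) or
  (1/m)·(#observed covariates of the subject)/p; by the row-duplication
  identity the uniform choice equals weight 1 for point estimates while
  keeping CV deviance on the per-subject scale.
* **Recalibration** (1-se models only; requesting it for optimal-λ models
  is a usage error): by score — γ's fitted per completion and averaged for
  separate-MI methods, once on the weighted stack for stacked methods; new
  intercept γ₀ + γ₁·β₀ so the recalibrated linear predictor is exactly
  γ₀ + γ₁·Z — or by unpenalized refit of the selected set (same
  per-completion/stacked split).  Score recalibration preserves
  coefficient ratios to 1e−12 and validation AUC exactly.

Pooling always happens before prediction: a fitted model is one intercept
plus one slope vector, never an ensemble of m prediction sets.

## External evaluation and aggregation

Each model is scored on a fresh fully observed validation set (default
n = 5000) from the same mechanism: AUC with the Mann–Whitney tie
convention (ties count ½), Brier score, and counts of selected true
(x4–x10) and noise covariates.  One fresh validation set is drawn per
replicate to avoid coupling replicates through a shared benchmark.
Scenario summaries report per-variant means, empirical SDs, and
normal-approximation CI half-widths 1.96·SD/√reps, plus empirical EPV
(events = smaller outcome-class count; parameters = p + 1, intercept
included) and missingness/complete-case rates.

## Internal validation

`optimism_correct` implements the enhanced bootstrap for the *whole* MI
pipeline: bootstrap resampling is at subject level on the incomplete data,
before any imputation; each resample is re-imputed and re-modelled; the
bootstrap model is scored on its own m bootstrap completions (apparent_b)
and on the m original completions (test_b), metrics averaged over
completions first, then over bootstrap samples; corrected = apparent −
mean(apparent_b − test_b), an exact identity in the returned object.
Failed bootstrap replicates are skipped and the effective B reported.

## Reproducibility and replication scales

Every stochastic stage consumes a child generator derived from a master
seed via numpy `SeedSequence` spawn keys, so scenario results are
independent of execution order and bit-reproducible.  The acceptance
experiments use: 100,000 subjects for generator-level rates; 200
replicates for EPV bookkeeping; 100 replicates for the n = 200 / 50 %
missing / m = 10 external-validation comparison; and 100 replicates at
n = 600 / 10 % missing with m = 10 and B = 2 for the selection-ordering
experiment (a B = 25 sensitivity check gave the same orderings; larger B
mainly smooths the frequency estimates).  These scales keep a full run in
the tens of minutes on one CPU while leaving Monte-Carlo error well below
the effect sizes of interest.

## Limitations

* The generator's empirical prevalence (≈ 66 %) exceeds the ≈ 60 % quoted
  for this design (see above); quantities tied to prevalence — EPV,
  complete-case rates, absolute Brier levels — shift accordingly, and at
  n = 600 the resulting extra information makes the 1-se lasso methods
  sparse enough that backward elimination on bootstrap data is *not* the
  most parsimonious method here (mean model sizes ≈ 8.5 vs ≈ 7.3–7.6),
  although the optimal-vs-1-se noise ordering holds for every method pair.
* The synthetic mechanisms emulate correlated mixed-type covariates with
  sparse effects and MAR missingness with a shared per-subject propensity.
  They do not emulate nonlinear effects, interactions, measurement error,
  MNAR missingness, or per-variable missingness models, so passing tests
  certify the machinery under these conditions, not performance on any
  particular real dataset.
* Imputation models are main-effects linear/logistic only (no polytomous
  models, no passive imputation); cycles = 5 and donors = 5 are
  conventional defaults, exposed as parameters.
* Frequency-based methods depend on the 50 % threshold; internal
  validation of those methods would require a double bootstrap, which is
  out of scope.
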