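# Methods

## Estimands and model

`medscreen` targets the mediation decomposition of the average effect of a
binary exposure `A` (case status) on a continuous trait `Y`, with a
continuous, non-negative activity mediator `M` and confounders
`W = (age, sex)`.  Writing `ψ(a, a′) = E[Y(a, M(a′))]` for the mean
outcome when exposure is set to `a` while the mediator takes the value it
would naturally have under exposure `a′`:

- NDE `= ψ(1,0) − ψ(0,0)`,
- NIE `= ψ(1,1) − ψ(1,0)`,
- TE `= ψ(1,1) − ψ(0,0) = NDE + NIE` (the mediation formula, exact because
  `ψ(1,0)` is shared between the two contrasts).

Identification of the natural estimands requires consistency/no
interference, joint exchangeability of exposure and mediator given `W`,
exposure and mediator positivity, and cross-world counterfactual
independence.  None of these is testable from data and the last is not
even experimentally verifiable; the package therefore treats its outputs
as statistical contrasts adjusted for `W`, not causal claims.  The
synthetic generator, by construction, satisfies all of them, which is what
makes it a meaningful test bed.

## One-step estimation

Each `ψ(a, a′)` is estimated as the sample mean of the uncentered
efficient influence function

```
D_i = 1{A_i=a}/g(a|W_i) · r(M_i, W_i) · (Y_i − μ(a, M_i, W_i))
    + 1{A_i=a′}/g(a′|W_i) · (μ(a, M_i, W_i) − η(a′; a, W_i))
    + η(a′; a, W_i)
```

with nuisances

- `g(a|w) = P(A=a|W=w)` — exposure propensity,
- `e(a|m,w) = P(A=a|M=m,W=w)` — mediator-conditional propensity,
- `μ(a,m,w) = E[Y|A=a,M=m,W=w]` — outcome regression, fit separately per
  exposure arm,
- `η(a′;a,w) = E[μ(a,M,W)|A=a′,W=w]` — pseudo-outcome regression: `μ(a,·)`
  evaluated at the observed `(M_i, W_i)` and regressed on `W` among the
  `A=a′` subsample.

The mediator density ratio `p(m|a′,w)/p(m|a,w)` is handled through the
Bayes reparameterisation `r = [e(a′|M,W)/e(a|M,W)] · [g(a|W)/g(a′|W)]`,
which replaces conditional density estimation for the continuous mediator
with a second binary regression.  When `a = a′`, `r ≡ 1` and the estimator
reduces to AIPW for `E[Y(a)]`.

This is a one-step (plug-in + mean of the estimated influence function)
construction: with saturated empirical-frequency nuisances on discrete
data the correction term averages to exactly zero and the estimator
coincides with nonparametric g-computation, which the tests verify to
1e-10.  The total effect is additionally estimated by plain AIPW,
`mean[(A/g₁ − (1−A)/g₀)(Y − b(A,W)) + b(1,W) − b(0,W)]` with
`b(a,w) = E[Y|A=a,W=w]`, on the larger sample that requires no mediator
measurement.

Inference is Wald throughout: `se = sd(D − ψ̂, ddof=1)/√n`, normal (not t)
reference distribution, `ci95 = point ± 1.96·se`.  Constant influence
values yield `se = 0` and a degenerate-inference warning with `p`
reported as 0.  Contrast estimates (NDE, NIE, TE) use differences of the
component influence functions, so the decomposition identity
`NDE + NIE = TE` holds to floating-point rounding on every input.

## Nuisance estimation: Super Learner with cross-fitting

Nuisances are fit by a convex stacked ensemble.  Held-out predictions for
each base learner are assembled over `K` folds (stratified on the
exposure for binary targets); meta-weights are chosen by non-negative
least squares on the held-out predictions, renormalised to the simplex,
and then compared on cross-validated risk (MSE for continuous targets,
mean negative log-likelihood for binary) against every single-learner
vertex — the risk minimiser wins, with ties broken toward the stack and
then toward earlier learners in library order.  This candidate-set step
guarantees the ensemble's CV risk never exceeds the best single
learner's, a contract asserted on every fit.  Base learners that fail on
any fold (e.g. a classifier given a constant outcome) are dropped with a
warning rather than aborting a many-trait screen; if all fail, the fit
errors.

Library presets:

| preset       | members                                             | use |
|--------------|-----------------------------------------------------|-----|
| `default`    | spline regression, lasso, GLM with two-way interactions, gradient boosting (lightgbm) | main screens |
| `glmnet`     | lasso alone                                         | no-stacking baseline |
| `fast`       | unpenalised GLM                                     | simulation studies |
| `fast_stack` | GLM + marginal mean                                 | fast screens with a real meta-step |

The adaptive-splines slot is a penalised regression on a B-spline basis
(scikit-learn `SplineTransformer` + ridge); the boosting slot uses
lightgbm with its library defaults, which the run manifest records by
version.

Cross-fitting is on by default for all nuisances: each subject's
predictions come from fits excluding that subject's fold (the folds are
shared across nuisances within a fit).  This is what licenses Wald
intervals around adaptive nuisance estimates; a no-cross-fit toggle
exists for comparison.  Within each training split, the pseudo-outcome
for `η` is computed from the same split's `μ` fit, keeping the nested
regression honest.

Fold construction deals shuffled label groups cyclically with a pointer
that continues across groups, so overall fold sizes and per-label fold
counts simultaneously differ by at most one.  A stratum smaller than `K`
cannot reach every fold and is spread over a random subset with a logged
warning.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` | 10 main workflow, 20 + stratification for small-cohort replication configs, 5 in the fast simulation studies | CV folds, shared by stacking and cross-fitting |
| `delta` | 0.025 | symmetric truncation of `g` and `e` into `[δ, 1−δ]`; bounds the inverse weights and is recorded in the manifest.  Must be chosen against the design: at a ~6% case fraction a 0.025 bound already binds for low-propensity subjects and visibly biases the mediation contrasts, which is why the bundled analyses use 0.01 there |
| `clip_eps` | 0.001 | clipping of binary-family predictions at `sl_predict` time, keeping density ratios finite |
| `fdr_threshold` | 0.05 | BH step-up level |
| `family_mode` | per-analysis | BH families are (stratum × estimand × mediator); a global mode pools everything |
| `te_fraction_floor` | 1e-8 | \|TE\| below this leaves NDE/NIE fractions undefined rather than reporting meaningless ratios |

Multiplicity families default to the per-analysis reading — each
(stratum × estimand × mediator) combination adjusted separately — the
most conservative structure consistent with reporting significance per
analysis; the choice is echoed in the manifest.  TE rows in the screen
use the AIPW estimator on the TE-eligible sample (complete cases on
confounders, exposure, outcome), while decomposition fractions come from
the shared-nuisance mediation run where `NDE + NIE = TE` is exact — the
two choices coexist because the two complete-case sets legitimately
differ.

## Synthetic cohorts

The generator is a linear SEM: `A ~ Bernoulli(expit(γ₀ + γ_age·age +
γ_sex·sex))` with age ~ Uniform[40, 69] (a typical adult biobank
recruitment window) and sex ~ Bernoulli(0.73 female); `M = α₀ + α_A·A +
α_age·age + ε`, σ_M = 14 min/day, floored at 0; `Y_t` linear in
`(A, M, W)` with unit noise.  Defaults put the control mediator mean near
55 and the case mean near 44 min/day (α_A = −11.3) and draw direct
effects with standardised magnitudes 0.2–0.5 — small-to-medium shifts, the
regime the screening problem lives in.  Special questionnaire responses
("do not know"/"prefer not to answer") are encoded as sentinel codes −1
and −3, declared in config and negative by construction so they cannot
collide with valid durations; missingness is MCAR per column, never
touching the exposure.

Truths are closed-form (`NDE = β_A`, `NIE = β_M·α_A`) with mediator
flooring disabled; a brute-force counterfactual simulator (simulate
`Y(1,M(0))`, `Y(0,M(0))`, `Y(1,M(1))` at n = 10⁶ and difference the
means) provides the independent oracle, and validation regimes keep the
flooring probability below 0.1% so the closed forms remain exact to
within Monte-Carlo error.  Two presets matter: `study_like_config`
(fixed case/control margins with strong imbalance, rejection-sampled so
the confounding structure survives) and `validation_config` (~30%
exposure prevalence).  The validation preset exists because propensity
truncation must not bind when measuring estimator bias and coverage;
with rare exposure the truncated estimator is a different (deliberately
stabilised) quantity.

What the generator does **not** emulate: heaping of self-reported minutes
at multiples of 5/10, non-linear confounder effects, informative (MNAR)
missingness, assay QC structure (modelled as upstream missingness),
longitudinal visits beyond a simple repeated-measurement averaging mode,
and real between-trait correlation.  Passing tests therefore demonstrate
that the estimators and workflow are correct under the stated model, not
that any particular real-data conclusion transfers.

## Numerical choices and degenerate inputs

- Winsorization clips at the nearest order statistic *inside* the band
  (`np.quantile` with `method="higher"`/`"lower"`).  Interpolated
  (type-7) bounds look natural but are not idempotent: clipped mass at
  the bound drags a re-computed interpolated quantile further inward, so
  winsorizing twice keeps moving data.  Order-statistic bounds are fixed
  points, and idempotence, monotonicity and the quantile-bound property
  all hold exactly.  The convention is recorded in the manifest.
- TyG uses `ln(TG[mg/dL] · glucose[mg/dL] / 2)` with mmol/L inputs
  converted by 88.57 (TG) and 18.018 (glucose); a unit switch supports
  either input convention, and non-positive inputs go missing rather than
  erroring.  Composites are missing whenever any component is; with
  repeated measurements, composites are computed per contemporaneous
  component pair first and averaged per subject afterwards.
- Cohen's d uses the pooled-SD form; zero pooled SD reports missing with
  a warning.  Welch's t uses the Welch–Satterthwaite df and the t
  reference distribution.
- BH adjustment delegates to `statsmodels` `multipletests(method="fdr_bh")`
  behind a wrapper that excludes missing p-values and reinserts them as
  missing; a hand-written brute-force step-up implementation serves as
  the independent cross-check in the tests.
- Per-(trait × stratum × mediator) sub-seeds are derived from the run
  seed via a CRC mix (kept below 2³¹), so screens are deterministic and
  insensitive to trait ordering.
- Estimation errors at the trait level (a stratum with no cases, an empty
  complete-case set, a degenerate training fold) surface as rows with
  missing estimates and a logged reason; the screen itself completes.

## Problem sizes

The validation suite runs the recovery study at 200 replicates of
n = 5,000 with the `fast` library and K = 5, the null-NIE calibration at
20 replicates × 50 traits of n = 1,500, the saturated-oracle check at
n = 500, and the brute-force FDR comparison over 1,000 random vectors —
sizes chosen so the whole suite exercises every claim at useful precision
while remaining a routine desk run.  At these sizes the observed behaviour
is comfortably inside the asserted bands (bias within 3 Monte-Carlo SEs of
zero, CI coverage ~94–96%, null-NIE false-discovery fraction ≤ nominal).

## Known limitations

- Natural (not interventional/randomized) mediation estimands only; a
  single mediator per run (multi-mediator analyses are separate runs per
  mediator); no TMLE variant; no survival outcomes.
- Rare-exposure designs interact with truncation as described above; the
  package reports the truncation level rather than adapting it.
- The Highly Adaptive Lasso is not in the learner registry; the generic
  `LearnerSpec` interface accepts any fit/predict object should one be
  needed.
- GO-term enrichment and any annotation-database post-processing of
  significant traits are out of scope.
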