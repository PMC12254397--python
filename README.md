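# medscreen

Semiparametric mediation screening of blood biomarkers: does a disease
affect molecular and cellular blood traits *directly*, or only through the
reduced physical activity that accompanies it?

`medscreen` is built for case/control biobank-style studies of a binary
exposure `A` (case status), an activity mediator `M` (e.g. minutes of
walking per day), confounders `W = (age, sex)` and many continuous trait
outcomes `Y`.  For every trait it decomposes the average effect of case
status through the counterfactual means `ψ(a, a′) = E[Y(a, M(a′))]`:

- **NDE** `= ψ(1,0) − ψ(0,0)` — natural direct effect, through all paths
  *not* involving the mediator;
- **NIE** `= ψ(1,1) − ψ(1,0)` — natural indirect effect, transmitted
  through the mediator;
- **TE** `= ψ(1,1) − ψ(0,0) = NDE + NIE` — the total (average) effect.

Each `ψ(a, a′)` is estimated with a one-step efficient estimator: the
sample mean of the (uncentered) efficient influence function

```
D = 1{A=a}/g(a|W) · r(M,W) · (Y − μ(a,M,W))
  + 1{A=a′}/g(a′|W) · (μ(a,M,W) − η(a′;a,W)) + η(a′;a,W),

r(M,W) = [e(a′|M,W)/e(a|M,W)] · [g(a|W)/g(a′|W)]
```

where `g` is the exposure propensity, `e(a|m,w) = P(A=a|M=m,W=w)` the
mediator-conditional propensity (a Bayes reparameterisation that avoids
density estimation for the continuous mediator), `μ` the outcome
regression and `η(a′;a,w) = E[μ(a,M,W)|A=a′,W=w]` the pseudo-outcome
regression.  Nuisances are fit by a cross-validated stacked ensemble
(Super Learner) with cross-fitting, so Wald confidence intervals
`point ± 1.96·sd(D)/√n` remain valid with adaptive learners.  The total
effect additionally gets the classic AIPW (doubly robust) estimator on the
larger sample that needs no mediator measurement.  Screens over many
traits are controlled with Benjamini–Hochberg FDR at 0.05 per analysis
family, and the package ships the surrounding workflow: composite
insulin-resistance indices (TyG, TG-to-HDL-C ratio), winsorization,
complete-case and questionnaire-response filtering, repeated-measurement
averaging, sex-stratified z-score concordance, NDE/NIE decomposition
fractions, matched case-subgroup comparisons and definition-stringency
sensitivity analyses.

Because real biobank inputs are access-controlled, the package includes a
first-class synthetic-cohort generator (`medscreen.synthetic`): a linear
structural equation model with age/sex confounding, a non-negative
activity mediator shifted downward in cases, configurable case/control
imbalance, missingness and special questionnaire response codes — with
analytically known true effects (`NDE = β_A`, `NIE = β_M·α_A`), so every
stage of the pipeline is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (400 cases, 6000 controls, 20 traits, mediator means 43.1 vs 55.4
min/day for valid responses):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screen_traits.py
```

prints

```
significant traits per (stratum x estimand) family (FDR < 0.05):
estimand  NDE  NIE  TE
stratum
combined   19    1  20
female     19    2  20
male        7    0  11
```

All 20 traits carry a genuine direct effect (standardised shifts 0.2–0.5),
and the screen finds nearly all of them in the combined and female
analyses (the male stratum is smaller, hence less powered).  Only 4 of the
20 traits have any mediated path at all, and those paths are small: the
lone significant combined-analysis NIE is one of those 4, so the
biomarker signal is *not* explained by the activity difference — exactly
the distinction the estimator exists to draw.  `03_concordance_and_fractions.py`
then reports female-vs-male z-score correlations (r = 0.89 for TE, 0.87
for NDE on this cohort) and per-trait NDE/NIE fractions of the total
effect; `04_pem_subgroup.py` runs the matched symptom-subgroup comparison
(disjoint control halves, 183 cases per arm, cross-arm concordance
r = 0.93, no significantly opposing traits); `05_sensitivity.py` re-screens
under 0.5%/1% winsorization, a no-stacking (penalised-GLM-only) library
and a diluted case definition (same 20 significant traits throughout;
|z| shrinks for 90% of traits under the diluted definition).

The same workflow is available as a CLI:

```bash
medscreen simulate --seed 3 --out results/sim
medscreen screen --input results/sim/cohort.tsv --seed 1 --out results/screen
medscreen report results/screen/results.tsv
```

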