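# Methods

This note records the statistical model, the defaults and the numerical
choices behind `deprisk`, and what the synthetic-data experiments do and do
not demonstrate.

## Phenotype model

Symptom records carry two core indicators (depressed-or-irritable mood;
anhedonia), a secondary-symptom count (0–7) and a suicidality flag, as a
current-or-past union per wave and reporter. MDD is coded by the symptom-
count rule: at least one core symptom and at least five symptoms in total
(cores counted individually). The ordinal DS grade is:

* **severe** — both cores with ≥3 secondary symptoms, or any suicidality;
* **moderate** — 7–8 total symptoms, or ≥1 core with ≥2 secondary;
* **mild** — 5–6 total symptoms, or ≥1 core with ≥1 secondary.

The mild/moderate criteria overlap by construction (one core plus two
secondary satisfies both), so grades are evaluated severe → moderate → mild
and the highest satisfied grade wins. This makes the scale monotone: adding
any symptom never lowers the grade (verified exhaustively over all 64 item
combinations). A consequence worth noting: any record satisfying the MDD
rule has ≥1 core and ≥3 secondary symptoms and therefore grades at least
*moderate*; "mild MDD" is unrealizable under these rules, and the synthetic
generator draws case grades from {moderate, severe} accordingly.

Incident MDD is no-case-at-baseline and case-at-follow-up; increased DS is
a ≥1-step grade rise. Both are computed per reporter; the exclusion cascade
removes baseline cases for whichever reporter's outcome is analysed.

The exact item-to-criterion mapping of the source instrument is
configurable rather than hard-coded: the coder consumes generic core /
secondary / suicidality columns, so a user with instrument data maps items
to those columns upstream.

## Predictors

Eleven categorical predictors with fixed reference levels (male, white, no
trauma, best caregiver relationship, least conflict). Dichotomizations
follow the matched definitions: school disengagement requires *both*
school-attitude items endorsed; the three behaviour items are positive when
endorsed "sometimes or often"; substance use is a union over all
substances; trauma is 0/1/2+ events. The two caregiver-relationship scores
and the family-conflict score are continuous scales split into quintiles by
the empirical 20/40/60/80 percentile ranks. Orientation differs by scale:
higher caregiver acceptance means a *better* relationship (category 1),
higher conflict a *higher* category. Tied scores at a boundary share the
lower category (min-rank convention) — documented because it decides
category sizes under heavy ties; a brute-force percentile-rank oracle in
the tests pins the behaviour.

## Synthetic cohort generator

The generator is a pure function of its config and seed and emulates the
structure the analysis assumes, not any real joint distribution:

* **Scale and nesting.** Defaults: 11,800 enrolled participants across 21
  sites; 11,166 families (the surplus participants are siblings placed into
  random families); 88% attend the follow-up wave. After the cascade this
  yields an analytic sample of ≈7,700 unrelated participants — the scale at
  which the motivating analysis operates.
* **Predictors** are drawn independently per participant from configurable
  marginals (defaults mirror a typical control column: 47.3% female, 43.5%
  non-white, rare behaviour flags down to 0.4%, quintiles at 20% each).
  Independence is a deliberate simplification: no predictor covariance is
  modelled, so collinearity behaviour in real data is untested.
* **Outcome.** Incident MDD at follow-up is Bernoulli(expit(β₀ + Σβ +
  site effect)), with Gaussian site intercepts (SD 0.3 by default) on the
  log-odds scale. The shipped truth coefficients have realistic log-odds
  magnitudes (0.15–1.45); the intercept is solved deterministically —
  the joint distribution of the coefficient sum over independent predictors
  is enumerated exactly and the intercept root-found — so the marginal
  incident prevalence is 0.8%, the regime the method must survive
  (site effects perturb this only in second order).
* **DS grades.** Non-cases draw grades from a mostly-asymptomatic control
  distribution (95.5% none); at follow-up the odds of any sub-threshold
  symptoms are tilted by the participant's centred risk score
  (`ds_risk_link`, default 0.5), so symptom worsening tracks the same
  predictors as incident MDD and cross-outcome evaluation shows genuinely
  above-chance discrimination. Baseline MDD history occurs at 1.5%,
  independent of predictors — adequate for exercising the cascade, not a
  model of continuity of illness.
* **Items.** Given a latent (MDD, grade) state, an item pattern is sampled
  uniformly from the exhaustively enumerated combinations that code back to
  exactly that state, so phenotype coding round-trips the latent truth with
  zero error — by construction, which is the point: coding bugs cannot hide
  behind generator noise.
* **Reporters.** The parent record copies the youth latent state with
  probability `reporter_agreement` (default 0.05) per wave, else an
  independent redraw. At sub-1% prevalence this puts the coded youth–parent
  κ in the near-chance range (≈0.02–0.09 across seeds), the order observed
  for discordant informants on rare outcomes. Because both reporters share
  the participant's predictor-driven risk, κ sits slightly above the copy
  probability itself.
* **Missingness** is independent per baseline raw-measure cell (default
  1.5%, i.e. ≈21% listwise loss over 15 columns). It is missing-completely-
  at-random; informative missingness is out of scope, matching an analysis
  that only ever listwise-deletes.

## Validation metrics

AUC is Mann–Whitney concordance (ties ½). Its CI is a DeLong-variance
normal interval truncated to [0,1]; a stratified bootstrap CI is available
as a cross-check because the choice of interval method is not dictated by
the workflow. Calibration-in-the-large is the intercept of a one-parameter
logistic fit with logit(p) as fixed offset; the calibration slope is the
coefficient of logit(p) in a free logistic re-fit; curves use equal-count
deciles (no smoother). Probabilities are clipped to [1e-15, 1−1e-15] before
the logit.

Ranking metrics are computed on the intercept-free coefficient sum where
available. This is mathematically the same AUC (monotone invariance) but
numerically better: probability-scale rounding can merge near-ties, whereas
the coefficient sum is bitwise identical between a model and its
recalibrated copy — so "recalibration leaves AUC unchanged" holds exactly,
not approximately.

## Model updating

Recalibration fits a one-parameter logistic MLE with the coefficient part
of the linear predictor as offset (slope fixed at 1 by construction). Its
score equation forces calibration-in-the-large to zero on the same data,
and with a constant offset c and prevalence p the new intercept is exactly
logit(p) − c — both are test identities.

Refitting maximizes the binomial log-likelihood minus (λ/2)·Σβ² over all
non-intercept coefficients (categorical levels shrunk jointly; the
intercept is never penalized) by damped Newton iteration: step-halving
keeps the penalized objective non-decreasing, convergence is a gradient
max-norm below 1e-8, and an unpenalized fit whose slopes exceed 100 in
magnitude aborts with a separation diagnosis (saturated probabilities make
the score vanish, so a pure gradient test would "converge" at absurd
estimates). With λ > 0 estimates are finite even under complete separation.

The design matrix dummy-codes the 21 non-reference levels in a fixed
registry order and, in the interaction mode, appends all 191 pairwise
products of dummy columns from distinct predictors (pairwise is the minimal
reading of "all predictors and their interactions"; no three-way terms).

Penalty selection: for each bootstrap resample, every grid value is fit and
scored by an effective-AIC criterion — the unpenalized log-likelihood at
the penalized estimate minus the effective degrees of freedom, tr[(XᵀWX)
(XᵀWX + λD)⁻¹] — and the per-replicate argmax recorded; the selected λ is
the median over replicates, taking the lower middle value for even counts
so the selection always lies on the grid. Whether the criterion's
likelihood term should itself include the penalty is genuinely open; both
variants are implemented (`criterion="aic"` default, `"aic_penalized"`
alternative). Defaults: 15 log-spaced grid values in [0.01, 100] and 1,000
bootstrap replicates (the workflow-faithful setting; tests and examples use
5–50 replicates, which changes the selected λ little because the median is
stable). Single-class resamples are redrawn with a warning, capped at 100
attempts.

## Association analysis

One joint main-effects logistic model of all 11 predictors with a random
intercept per site (families are already deduplicated by the cascade; the
grouping column is configurable). Fitting is a profiled Laplace
approximation: for a candidate σ, penalized IRLS maximizes the joint
(β, u) objective; the Laplace criterion adds −½Σ log(σ²h_g + 1) with h_g
the per-group curvature; σ is optimized on this one-dimensional criterion
(bounded search on log σ) and compared against the σ→0 limit, a plain
logistic fit. Wald SEs come from the fixed-effect block of the inverse
joint penalized Fisher information — the standard Wald machinery for a
single random intercept, accurate for moderately sized groups and
cross-checked in the tests against an independent R implementation of the
same approximation. Known caveat: with very small groups or σ estimated
near the boundary the Laplace approximation understates uncertainty in σ
itself; fixed-effect inference is much less affected.

Odds ratios are exp(β) with exp(β ± z·SE) intervals; rare levels can have
effectively unbounded upper limits, which are reported honestly (and
serialized as null in JSON). FDR control is Benjamini–Hochberg across the
21 term p-values of one outcome's table; whether to pool both outcomes into
one family is left to a flag (default per-outcome).

## Problem sizes in the test battery

The simulation tests use sizes chosen to make their statistical assertions
sharp, as the package's own experimental design: marginal fidelity at
n=50,000 (3 binomial SEs), null-model prevalence at n=200,000, DeLong null
coverage over 1,000 replicates of n=500, parameter recovery over 20
replicates at n=20,000 with 5% outcome prevalence (where the ≥0.5 effects
are planted on predictors with 23–47% marginals so each is estimated with
SE ≈ 0.07, and 0.15 ≈ 2 SEs is a meaningful recovery bound), and CI
coverage for a planted OR of 4 over 100 replicates at n=20,000 with 21
sites. Penalty-selection sizes in tests (grids of 3–15 values, 5–50
bootstraps) exercise the same code path as the 1,000-bootstrap default.

## What passing tests do and do not show

Everything demonstrated on synthetic cohorts is conditional on the
generator's simplifications: independent predictors, MCAR missingness,
Gaussian site effects, no attrition process, no real covariance between
reporters beyond the agreement mixture, and symptom items sampled uniformly
within phenotype classes. Passing tests show the *procedures* are correct
(coding rules, cascade accounting, metric identities, estimator
consistency, CI coverage under the assumed model) — they do not certify
performance numbers on any real cohort, where predictor collinearity,
informative missingness and reporter structure will differ.
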