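# Methods

This note records the statistical model the package implements, the
numerical choices behind the estimator, what the synthetic cohort generator
does and does not emulate, and the known limitations. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The model

Recurrent time-loss injuries in a multi-team cohort are modelled as a
proportional-hazards process on a **gap-time exposure axis**: after each
return from injury the survival clock restarts at zero, and time is
measured in exposure hours — individual match minutes / 60 plus the
player's team's weekly group training hours, pro-rated by day overlap. A
player accrues no risk time while absent injured.

The hazard for player *j* of team *i* at gap time *t* is

    h_ij(t) = h0(t) · exp( x_ij(t)' β + u_i + v_ij ),

with `u_i ~ N(0, σ²_team)` and `v_ij ~ N(0, σ²_player)` independent
Gaussian intercepts on the log-hazard (log-normal frailties), players
nested within teams. Fixed covariates: age (years), height (cm), mass
(kg), position (forward/back), number of previous injuries in the dataset,
and the two rolling match-exposure variables —

* **12-month match exposure**: involvements of ≥ 20 minutes in the
  preceding 365 days (an integer count; the ≥ 20-minute rule is inclusive
  and both rolling windows are half-open, exclusive below and inclusive at
  the evaluation date);
* **1-month match exposure**: full-game equivalents (minutes / 80)
  in the preceding 30 days.

Continuous covariates are standardized to `(x − mean) / (2·SD)` so that
`exp(β)` is the hazard ratio per **two-SD** increase. Possible
non-linearity in the chronic-exposure effect is examined with quadratic
and cubic terms on a centred, SD-scaled basis; the interaction between
chronic and acute load enters as 12-month-exposure quartile × 1-month
exposure product terms (reference = lowest quartile).

## Risk sets and covariate measurement

Risk intervals are expanded to counting-process form: each gap-time
interval is split at weekly boundaries into `(start, stop]` segments on
the exposure-hour clock, each carrying the covariates current during that
calendar week. The Cox partial likelihood then compares, at every event's
gap time, the failing segment against all segments whose risk window
covers that gap time — so everyone's rolling exposures are time-updated,
not frozen at interval ends. A per-interval summary table with covariates
evaluated at the interval end date is also available
(`build_intervals`), but the fitted models consume the expanded rows:
with ~80% of intervals ending in an event, end-date evaluation samples
cases and comparators at systematically different kinds of time points
and the acute-load contrast collapses (measurably: a simulated effect of
known size is estimated at zero).

One measurement rule applies uniformly to cases and comparators: a
segment's rolling windows are anchored at the segment's match day when
the player was involved that week, and midweek otherwise. Anchor
uniformity matters — event windows end on injury (usually match) days, and
a 30-day window ending on a fixture day contains one more weekly fixture
than one ending on a week boundary; mixing anchors fabricates an
acute-load contrast of roughly +0.4 FGE between cases and comparators.

Two rules handle edge cases: intervals (segments) whose 12-month exposure
is zero are excluded from the risk sets and counted in the build report
(the event of an excluded interval still advances the player's
previous-injury history); an injury on the return day with no exposure
accrued keeps its event by flooring the duration at 0.01 h, while a
censored interval with no exposure is dropped (it can contribute to no
risk set).

## Estimation

Estimation is penalized partial likelihood with a Laplace-approximate
marginal likelihood, the standard approach for log-normal frailty Cox
models:

* **Inner loop.** At fixed variance components, Newton–Raphson maximizes
  `PPL(β, b) = pl(β, b) − b' Σ⁻¹ b / 2` jointly in the fixed effects and
  all random intercepts, with step-halving so the PPL never decreases.
  Ties use the Efron correction by default (Breslow available).
  Convergence: relative PPL change below 1e-8, at most 50 iterations.
  The observed information is computed exactly (including all
  team × player cross blocks) through prefix-sum accumulations over the
  distinct event times plus one rank-D downdate, which keeps a fit with
  ~550 random effects and ~2500 events below a second per Newton step.
* **Outer loop.** The integrated log-likelihood
  `ILL(σ²) = PPL(β̂, b̂) − ½ log det(I + Σ^{1/2} K Σ^{1/2})`, with K the
  random-effect block of the observed information at the mode, is
  maximized over log-variances by bounded derivative-free search
  (Brent for one component, Nelder–Mead for two; bounds
  log σ² ∈ [−12, 3]), warm-starting the inner loop between evaluations.
  A variance pinned at zero is held at a numerically negligible value
  (penalty ~1e13) so the nested model collapses exactly onto Cox PH /
  shared frailty — an identity the test suite asserts at 1e-6 relative
  tolerance on the coefficients.
* **Standard errors.** Fixed effects: inverse penalized information at
  the mode. Variance components: central-difference Hessian of the ILL on
  the log-variance scale, delta-method transformed. Confidence intervals
  are 90% (z = 1.6449) throughout, matching the reporting convention.
* **Model comparison.** `AIC = −2·LL + 2k`, `BIC = −2·LL + k·ln(events)`
  with LL the integrated log-likelihood (partial log-likelihood for Cox
  PH) and k counting fixed effects plus variance components — not
  effective degrees of freedom, a documented simplification. Differences
  above 2 are flagged substantial; likelihood-ratio tests for variance
  components use boundary mixtures (50:50 χ²₀:χ²₁ for one component;
  ¼:½:¼ χ²₀:χ²₁:χ²₂ for two), with significance at p ≤ 0.10. The
  Wald test reports the one-sided z = σ̂²/SE(σ̂²); the precise "modified"
  Wald variant used historically with this model family is not fully
  documented, so both Wald and mixture-LRT evidence are reported.
* **Polynomial degree.** Degrees 1–3 are fitted and the smallest degree
  within 2 AIC units of the minimum is chosen (`aic_margin` parameter;
  0 recovers plain AIC minimization). Plain minimization accepts a
  spurious extra degree with probability ≈ P(χ²₁ > 2) ≈ 16% per degree;
  the margin applies the same "substantial difference" convention used
  for model comparison.

## Magnitude-based inference

An effect's uncertainty is modelled as Normal on the log-HR scale with
`se = (ln CI_high − ln CI_low) / (2·1.6449)`. Thresholds: benefit
HR 0.90, harm HR 1.11 (source texts disagree between 1.11 and 1.10; the
1.11 value is adopted because back-computing the published quartile-2 row
reproduces its printed harmful likelihood of 31 with 1.11 but not with
1.10, and it remains a parameter). Unrounded percentages drive the
">5% in both directions ⇒ unclear" rule and the probabilistic qualifier
(<0.5 most unlikely / 0.5–5 very unlikely / 5–25 unlikely / 25–75
possibly / 75–95 likely / 95–99.5 very likely / >99.5 most likely);
display rounding is half-away-from-zero. Of the published worked
examples, seven of eight rows reproduce their printed labels exactly from
the rounded HR/CI inputs; the mass row computes a trivial likelihood
within one point of the printed 95 but on the "likely"/"very likely"
boundary, so its qualifier is sensitive to input rounding — the test
suite asserts its category and percentage band only.

## The synthetic cohort generator

No public data exist for this design (club medical records are
proprietary), so the generator is a first-class module that runs the
model forwards. It emulates: 12 teams × 45 players over 3 seasons
(scalable to 7), weekly Saturday fixtures September–May plus four midweek
rounds (40 fixture dates/season), a per-player squad-selection probability
drawn from a Beta distribution (mean 0.58, SD 0.26), match minutes from a
mixture (58% full 80-minute games, 12% 40–79, 18% 20–39, 12% cameos
under 20), team training hours ~ N(10, 1.5²) per week, covariates
age 26 ± 4 y, height 186 ± 8 cm, mass 102 ± 13 kg, 55% forwards, and
log-normal absence spells (median 10 days — the absence distribution is a
modelling choice, not an observed quantity). Injuries arrive by
exponential thinning on the exposure-hour axis with the hazard above;
the baseline is 0.003/h, and the default true effects are the published
point estimates read forwards (e.g. HR 1.14 per 3.2 FGE acute load,
×0.78 in the top chronic quartile, a cubic chronic-exposure log-hazard
crossing HR 1.11 near 15 and 35 involvements, σ²_team 0.05, σ²_player
0.2). Under these defaults the cohort shows ≈1.8 injuries/player-season,
12-month involvements ≈17 ± 9 (range 1–35), 1-month exposure
≈1.8 ± 1.3 FGE and ≈89% of players with recurrent injuries — close to
the published cohort summaries it is calibrated towards.

Determinism: each player owns an RNG stream spawned from the master seed,
so identical (config, seed) pairs are byte-identical and enlarging the
cohort does not perturb existing players' histories.

What it does **not** emulate — and hence what passing tests do not show
about real data: squad selection is independent of fitness and form (no
exposure–risk feedback); there is no match-intensity dimension
(collisions, GPS load) and no individual training load; injury severity
and diagnosis are not modelled (the OSICS field is a pass-through);
transfers between clubs are supported by the schema but not generated;
within a week the hazard is constant and covariates are refreshed weekly,
not continuously.

## Verification-harness design choices

* **Parameter recovery** (50 replicates at 12 × 45 × 3): the generator's
  previous-injury effect is off and the term omitted from the fitted
  model. The previous-injury count is endogenous — it accumulates from
  the same player frailty the model estimates — and including it shifts
  the σ²_player estimand well below the generating value (measured:
  ≈0.14 against a truth of 0.2, vs ≈0.18 for the correctly-specified
  design). The harness therefore tests the estimator on a
  correctly-specified model; the endogeneity of injury history in the
  full model is a property of the study design itself.
* **Polynomial-shape experiment**: detecting a *cubic* (as opposed to
  merely curved) exposure effect needs both tails of the exposure range
  populated; the experiment therefore uses a denser fixture calendar
  (47 dates/season, emulating cup/international involvement) with higher
  selection probabilities, and a cubic truth with the same anatomy as the
  default (elevated risk at both extremes, protective dip between) but a
  larger cubic component. The linear-truth arm uses the same cohort with
  a purely linear log-hazard.
* **Model-comparison experiment**: at desk scale (8 teams × 20 players ×
  2 seasons) a team variance of 0.05 is barely identified from 8 team
  intercepts, so the experiment generates σ²_team = 0.2, σ²_player = 0.3
  to give the ordering question (Cox vs shared vs nested) a determinate
  answer.

## Numerical details and degenerate inputs

* Linear predictors are max-shifted before exponentiation; the shift
  cancels exactly in the partial likelihood because the number of Efron
  columns equals the number of events.
* The Cholesky of the penalized information falls back to a jittered
  factorization (up to 1e-3) before declaring separation.
* Quartile breakpoints require ≥ 4 observations with ≥ 2 distinct values;
  degenerate (constant) exposure samples are an error, and fixed
  user-supplied breakpoints override data-derived ones (needed whenever
  published integer bin edges are to be reproduced).
* Zero-SD covariates cannot be 2-SD standardized (error, not silent).
* A model with no events, an interaction with an event-free stratum, and
  a nested structure with fewer than two teams are all errors.

## Known limitations

* The Laplace approximation slightly underestimates variance components
  with few events per cluster (visible as the mild downward bias the
  recovery suite measures); gamma-frailty EM and exact integration are
  out of scope.
* k in AIC/BIC counts variance parameters rather than effective degrees
  of freedom, so frailty-model AICs are mildly optimistic; only
  differences and orderings are interpreted.
* Published absolute LL/AIC/BIC values for the original cohort are on an
  unstated (likely null-relative) scale and are not comparable to this
  implementation's absolute values; only ordering and substantial-
  difference logic carry over.
* Calendar-time non-proportionality (season phase effects) is absorbed
  into the gap-time baseline only approximately.
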