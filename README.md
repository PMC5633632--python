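# matchrisk

Recurrent-event injury-risk modelling for team-sport cohorts: rolling
match-exposure covariates, gap-time risk intervals measured in exposure
hours, proportional-hazards models with nested (team ⊃ player) log-normal
frailties, and magnitude-based inference for 2-SD-standardized hazard
ratios. A synthetic multi-team cohort generator makes the whole pipeline
runnable and testable without access to proprietary club medical records.

**Who it is for.** Sports epidemiologists and biostatisticians analysing
longitudinal injury-surveillance data — rosters, match involvements,
weekly team training hours and time-loss injury records — who want to ask
how *accumulated* (12-month) and *recent* (1-month) match exposure relate
to current injury risk while accounting for repeated injuries within
players and clustering within teams.

## The model

Injuries are recurrent events on a **gap-time exposure axis**: the
survival clock restarts at each return from injury, and time is exposure
hours (match minutes/60 plus pro-rated weekly team training hours). For
player *j* of team *i*,

    h_ij(t) = h0(t) · exp( x_ij(t)'β + u_i + v_ij ),
    u_i ~ N(0, σ²_team),   v_ij ~ N(0, σ²_player),

with covariates age, height, mass, position, previous-injury count,
12-month match exposure (involvements of ≥20 min in the preceding 365
days; cubic polynomial allowed) and 1-month match exposure (full-game
equivalents, minutes/80, in the preceding 30 days), plus an optional
12-month-quartile × 1-month interaction. Continuous covariates are
scaled by twice their SD, so `exp(β)` is the hazard ratio (HR) per 2-SD
increase, reported with 90% CIs. Estimation is penalized partial
likelihood (Newton, Efron ties) with a Laplace-approximate marginal
likelihood maximized over the variance components; `random="none"`
reduces exactly to Cox PH and `random="player"` to the shared frailty
model, which supports LL/AIC/BIC comparison across the three structures.

Magnitude-based inference classifies each HR against smallest-worthwhile
thresholds (benefit HR 0.90, harm HR 1.11): the normal distribution on
the log-HR implied by the CI yields percentage likelihoods that the
effect is beneficial/trivial/harmful, an effect with >5% probability in
both directions is *unclear*, and clear effects carry a probabilistic
qualifier ("possibly", "likely", "very likely", "most likely", ...).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import matchrisk as mr
from matchrisk.frailty import ModelSpec, Term, FitControl, fit, hr_per_2sd, hr_curve
from matchrisk.intervals import build_counting_process, add_standardized
from matchrisk.mbi import mbi_from_fit

cohort = mr.simulate(mr.SimConfig(n_teams=6, players_per_team=30, n_seasons=3), seed=42)
rows, report = build_counting_process(cohort)
rows, scales = add_standardized(
    rows, ["age", "height_cm", "mass_kg", "prev_injury_count", "one_month_fge"])

model = fit(
    rows,
    ModelSpec(
        terms=("age_2sd", "height_cm_2sd", "mass_kg_2sd", "position",
               "prev_injury_count_2sd", "one_month_fge_2sd",
               Term("twelve_month_matches", 3)),
        random="team_player_nested",
    ),
    FitControl(outer_xatol=0.05, outer_maxfev=60),
)
print(model.sigma2_team, model.sigma2_player)
print(hr_per_2sd(model, "prev_injury_count_2sd"))
print(mbi_from_fit(model, "prev_injury_count_2sd").label)
print(hr_curve(model, "twelve_month_matches", grid=[5, 15, 25]))
```

On this 180-player, 790-event synthetic cohort the fit prints variance
components `σ²_team = 0.072 (SE 0.055)` and `σ²_player = 0.104 (SE
0.051)`; the previous-injury effect is `HR 1.33 (90% CI 1.18–1.49)` with
MBI likelihoods `0|1|99` — "very likely harmful" — meaning a 2-SD (≈6
injuries) greater injury history carries a third more instantaneous
injury risk, with 99% of the effect's probability mass beyond the harm
threshold. The recent-exposure effect prints `HR 1.07 (90% CI
0.93–1.23)`, covering its generating value, and the chronic-exposure
curve falls from `HR 1.48` at 5 involvements to `0.85` at 25 relative to
the cohort mean — the elevated-risk-at-low-exposure arm of the U-shape
(this cohort's fixture calendar rarely produces >30 involvements, so the
high arm is barely sampled).

The same pipeline runs from the shell:

```bash
matchrisk simulate --seed 42 --out cohort/
matchrisk build --cohort cohort/ --out intervals.csv
matchrisk fit --intervals intervals.csv --random team_player_nested --out fit.csv
matchrisk mbi --effects fit.csv --out mbi.csv
matchrisk run --config analysis.yaml --seed 42 --out results/   # all stages + manifest
```

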