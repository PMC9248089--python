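# Methods

## Model

Subjects move on the state space {1 NS, 2 CI, 3 PF, 4 CF, 5 death} in
continuous time under a time-homogeneous Markov process with generator
`Q`. Off-diagonal `q_rs` is the instantaneous per-year rate of an
`r → s` move; diagonals are `q_rr = −Σ_{s≠r} q_rs`; death has no exits.
Direct NS↔CF and CI↔PF transitions are structural zeros: each would
require two phenotype components (cognition and frailty status) to flip
at the same instant, an event of probability zero under continuous
observation. The CF state is still reachable from NS in any positive
time through CI or PF, so all one-year probabilities are positive.

Assumptions worth stating explicitly: homogeneity in time (intensities
do not change over the follow-up window), the Markov property (future
evolution depends only on the current state), exponential sojourns with
mean `−1/q_rr`, and covariate effects that are constant multipliers of
the baseline intensities (`q_rs(x) = q_rs⁽⁰⁾ exp(βᵀ_rs x)`, baseline
covariates only — no time-varying effects).

## Likelihood and death conventions

Panel data contribute, per subject, the product of
`P_{s_i, s_{i+1}}(t_{i+1} − t_i)` over consecutive observation pairs,
with `P(u) = exp(Qu)` computed by scaling-and-squaring with Padé
approximation (`scipy.linalg.expm`); a truncated power-series oracle is
kept in the test suite as an independent cross-check (agreement below
1e−10 on random generators). A subject with a single observation
contributes nothing.

Death times in exit-interview surveys are reported at the wave where
the death is discovered, so the default `death_convention="interval"`
treats a death like any other panel transition. The alternative
`"exact"` convention treats the recorded time as the true death time
and contributes the density `Σ_r P_{s_i,r}(Δt) · q_{r,death}`,
marginalising the unknown pre-death state. The simulator records death
at the first wave after the jump, matching the interval convention.

Observation pairs are aggregated by (covariate pattern, interval
length, from-state, to-state) before optimisation, so the per-iteration
cost is one matrix exponential per pattern × interval, independent of
cohort size.

## Estimation numerics

Intensities are parameterised as `log q_rs`, making positivity
structural; covariate coefficients enter linearly on that log scale.
Optimisation is L-BFGS-B with finite-difference gradients, bounds
[−12, 4] on log-rates and [−8, 8] on β, `ftol = 1e−12` (absolute
log-likelihood changes around 1e−8 at this problem's scale).
Initial rates are crude estimates — observed `r → s` pair counts over
person-years at risk in `r`, floored at 1e−3 — with 0.1 as the fallback
when a state carries no exposure. Non-convergence is flagged on the
result and warned about, never silent.

The covariance is the inverse of a central-finite-difference Hessian of
the negative log-likelihood at the optimum (pseudo-inverse with a
warning when singular). Intensity intervals are log-normal
(estimate ∓ 1.96 SE on the log scale, exponentiated), which matches the
asymmetry expected of small positive rates; hazard-ratio intervals are
Wald intervals on β. A transition the data carry no information about
is driven to the lower bound, reported with an effectively unbounded
interval and an explicit warning ("pinned") — typical for rare exits
such as CI→death when few subjects are ever observed in CI.

Duplicate observation times within a subject, observations after death,
and states outside the label set are data errors, not silently cleaned.

## Covariate screening

The two-step procedure first fits one candidate covariate at a time on
the four reported transitions (CI→CF, PF→CF progression; CF→CI, CF→PF
improvement), then jointly refits every covariate with a Wald p < 0.05
on **any** modelled transition in stage 1 (per-transition significance;
an overall test would be an alternative reading and is not used). No
multiple-testing correction is applied, mirroring common practice for
this two-step screen; that is a known limitation, and the `alpha`
argument is the only dial. An empty stage-2 selection returns the
stage-1 table with a note rather than failing.

## Goodness of fit and the LRT

Expected prevalence conditions on the observed baseline state
distribution: `expected(s, t) = Σ_r π_r(0) P_{r,s}(t)`. Observed
prevalence counts recorded states with deaths carried forward; the dead
stay in the denominator because death is a state of the model.

The Pearson-type statistic uses one cell per (from-state, to-state,
interval length): `Σ (obs − exp)² / exp` with `exp = n_{r,Δt} ·
P_{r,s}(Δt)`. Its null distribution under panel observation is not
chi-square, so the p-value comes from a parametric bootstrap: simulate
cohorts from the fitted generator on the cohort's wave grid (same
baseline states), refit each (initialised at the fitted rates), and
take the exceedance fraction with the usual +1 correction. Bootstrap
replication count defaults to 200 (50 in the calibration tests).
Zero-expectation cells are skipped with a warning. The bootstrap uses
the full wave grid for every subject, so cohorts with informative
dropout are outside its remit.

Likelihood-ratio tests compare nested transition structures (e.g.
freeing the NS↔CF intensities adds exactly two parameters, df = 2)
against chi-square(df). When the nested model's extra rates are truly
zero the truth lies on the boundary of the enlarged parameter space, so
the chi-square reference is conservative — simulated null G values sit
well below chi-square(2) quantiles, and the calibration test asserts
the absence of anti-conservative inflation rather than exact uniformity.
Small negative G from finite optimizer tolerance (|G| < 0.01) is
clipped to zero; anything larger raises.

## Descriptive conventions

The incidence rate of CF is new CF cases among baseline-CF-free
subjects over person-years; the improvement rate is the mirror image
for baseline-CF subjects. Published per-100-person-year figures of this
kind rarely state their exposure accounting, and the printed counts
here (239/3584 over four years, 213/467) do not reproduce the reported
1.70/11.90 under the naive full-exposure convention (they give
1.67/11.40), so three conventions are offered explicitly: `full`
(at-risk count × span), `censor_death` (default; death contributes
exposure to the interval midpoint), and `censor_event` (additionally
censor at the first-event interval midpoint). "CF at follow-up" reads
the state at the final wave; deaths before the final wave count as
deaths in follow-up distributions and mortality.

Baseline tables use one-way ANOVA for continuous variables and the
chi-square test of independence for categoricals (`scipy.stats`).

## The simulator

`simulate_cohort` draws exact competing-risks trajectories: holding
time ~ Exponential(−q_rr), next state with probability q_rs/(−q_rr),
read off at the wave times (the vectorised path advances all subjects
interval by interval; the single-subject `simulate_trajectory` returns
the full jump list). Defaults are the study conditions everything else
is validated under: 4051 subjects, baseline mix 1441/142/2001/467,
waves at 0/2/4 years, the reference intensities, and independent binary
covariates at their marginal prevalences (CHARLS-like joint structure
is not emulated; a correlated-covariate design would need to replace
`draw_covariates`). Age-band shares (70/24/6% for 60–69/70–79/80+) are
chosen to match a 60+ cohort with mean age ≈ 67, SD ≈ 6. Dropout, when
enabled, is monotone attrition: once a wave is missed the subject never
returns.

`simulate_raw_measures` generates component measures that land on the
correct side of the supplied cut-offs and norms, so the phenotype
pipeline reproduces the latent states *exactly* when run with those
same tables. That round-trip identity is a correctness check of the
scoring logic, not a realism claim: real measures sit near their
cut-offs, misclassify, and miss at random, none of which is emulated.
Likewise the generated CESD item scores (exhaustion) and CESD totals
(depression) are drawn independently rather than from a joint item
model. Passing phenotype tests therefore demonstrate correct rule
implementation, not robustness to noisy measurement.

Grip and gait cut-offs are population-specific and not universal
constants; the shipped defaults follow the original Fried convention
(gender × BMI-quartile grip in kg, gender × median-height walking speed
in m/s) and are meant to be replaced via `CutoffTable`/YAML for any
real cohort. Cognition norms default to within-sample age-band mean/SD
(computed on baseline records passing the completeness screen) and
accept external normative tables; the boundary case "exactly 1 SD
below" is *not* impairment (strict inequality), sleep of exactly 6 or
9 hours is intermediate (closed interval), and a subject missing any
cognition subscore or frailty component at any living wave is excluded
entirely, with a logged reason (complete-case analysis).

## Validation problem sizes

Simulation-based checks run at sizes chosen to make sampling error
small relative to the tolerances while keeping the default suite quick:
parameter-recovery coverage uses 20 cohorts of 4000 (pooled CI coverage
≥ 85%, relative bias ≤ 10% for rates ≥ 0.05/yr; the tiny rates
NS→death 0.008 and CI→death 0.005 are near the information boundary at
these sizes and are excluded from the bias check); hazard-ratio
recovery uses 10 cohorts of 4000; goodness-of-fit calibration uses 100
model-true replicates of 1000 subjects at 50 bootstrap draws; LRT null
calibration uses 50 replicates of 1000. Monte-Carlo/analytic agreement
is asserted at 3 binomial standard errors.

## Known limitations

- Time-homogeneous intensities only; no hidden/misclassified states,
  no semi-Markov sojourns, no time-varying covariates.
- Survey design (weights, household clustering) is out of scope; all
  cohort summaries are unweighted.
- The bootstrap GOF refits the baseline model only (covariate models
  are rejected with `NotImplementedError`).
- Wald/log-normal intervals are asymptotic; for transitions with very
  few informative observations they can be degenerate (pinned rates).
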