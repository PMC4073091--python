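# Methods

## Observer model

On each trial of a target task the true outcome (stop or landing position)
is `x`, the goal is `t`, and the participant reports `x_est`. The observer
holds a Gaussian prior over outcomes, N(t + shift_prior, sigma_prior^2), and
receives Gaussian evidence N(x + d * shift_evidence, sigma_evidence^2),
where `d` is the motion direction (+1/-1) when the evidence shift is
direction-coupled. The report is the posterior mode,

    x_est = w (t + shift_prior) + (1 - w)(x + d shift_evidence),
    w = sigma_evidence^2 / (sigma_prior^2 + sigma_evidence^2).

**Report likelihood.** The report distribution given the truth is
N(mean above, ((1 - w) sigma_evidence)^2): the evidence noise propagated
through the weighting, with no separate motor/pointing-noise term. A
separate report-noise SD would be unidentifiable from the two observables
the data expose per cell (the regression slope, which fixes w, and the
residual SD, which fixes (1 - w) sigma_evidence), and the model family fits
exactly two SD parameters per cell. This likelihood is the unique
two-parameter Gaussian consistent with the posterior-mode equation. Since a
Gaussian posterior is symmetric, any symmetric cost function (mean squared
error, absolute error, etc.) yields the same report, so the mode is not a
loss-function commitment.

Two useful identities follow and are enforced/tested throughout:

* estimation error = -w * performance error (population regression), so the
  empirical weighting is exactly the negative OLS slope;
* residual variance of that regression = (1 - w)^2 sigma_evidence^2.

## Parameter tying and model family

A `ModelSpec` ties `sigma_evidence` across any of {condition, direction,
feedback level} and `sigma_prior` across condition, and optionally frees the
shift parameters (one `shift_prior` and one `shift_evidence` per condition;
the evidence shift changes sign with motion direction). The prior mean is
always parameterised as target + shift_prior, so "prior mean fixed at the
target" is the shifts-off special case. Free-parameter counts are pure
functions of the spec and the factor levels present in the data; the
shipped presets give 4 (separate prior and evidence per condition), 3
(evidence tied across conditions), 3 (prior tied), and — for the
bidirectional task with shifts — 10 (evidence per condition x direction)
and 8 (evidence tied across direction).

## Fitting

Maximum likelihood by L-BFGS-B over log-SD (and raw shift) coordinates with
an analytic gradient; box bounds log sigma in [ln 0.1, ln 1e9] px, shifts in
+-2000 px; convergence tolerance 1e-8 nats; multi-start with 8 restarts by
default. The first start is data-driven: a no-intercept regression of
estimation on performance error per cell gives w and the residual SD, which
invert to starting SDs; the remaining starts draw SDs log-uniformly from
[1, 1e4] px.

**Flat priors.** Once w is ~0 the likelihood is an almost-flat plateau in
sigma_prior and strict ML may stop at an arbitrary large-but-finite value.
After optimisation, any prior SD whose NLL at the upper bound is within 0.5
nats of the optimum (below the one-sigma likelihood region for a single
parameter, hence statistically uninterpretable) is resolved to the bound, and
`classify_flat` then flags priors with SD > 1e7 px (strict). Flagged
participants are excluded from parametric SD contrasts but retained in
rank-based correlations. A consequence worth knowing: a truly flat generative
prior whose sampled weight lands more than ~1 SE above zero still fits at a
large finite SD and is *not* flagged; such fits make the group mean of
|prior SD - performance SD| heavy-tailed, which is why the qualitative
checklist summarises that contrast by the per-participant majority rather
than the mean (the paired t-test is still reported).

**BIC.** bic = k ln(n) + 2 nll with n = the number of non-excluded trials
entering that fit (both conditions for tied models — the participant's
dataset). Strong evidence at |dBIC| >= 6, inclusive. Degenerate data (zero
performance-error variance) raise a fit error rather than fitting silently
at an SD boundary.

**Bootstrap.** Percentile CIs from resampling trials with replacement within
participant x condition cells (preserving the design; the resampling unit is
a convention choice), refitting each replicate warm-started at the original
optimum. Default B = 5000 with alpha = 0.05; the pipelines' test profile
uses B = 500. Intervals are widened, if necessary, to contain the point
estimate. More than 50% replicate failures is an error.

## Trial preparation

Exclusions flag (never delete) trials whose estimation time deviates more
than 2 SD from the cell mean (two-sided, |t - m| > 2s, mean/SD over all
trials of the participant x condition (x task) cell, so re-application is a
no-op), and agent trials whose reaction time does likewise. SD = 0 cells
exclude nothing (strict inequality). The regression of estimation error on
performance error is plain OLS with intercept; `weighting` is defined as
exactly `-slope`.

## Group statistics

t tests and correlations delegate to scipy; the partial correlation
residualises both variables on the covariate by OLS (rank-transforming all
three first for the Spearman variant — a convention choice; p from the t
approximation with df = n - 3); the one-way repeated-measures ANOVA computes
the Greenhouse-Geisser epsilon from the double-centred covariance of the
level scores, with corrected dfs eps(L-1) and eps(L-1)(n-1). These two are
hand-written so that an independent reference implementation (pingouin)
can serve as the oracle in the tests. The median split orders participants
by self prior SD and assigns ties at the median — and the median participant
when n is odd — to the lower (narrow-prior) group. Bonferroni adjustment is
min(1, m p) within each reported contrast family.

One degenerate-input convention: a one-sample t of values all exactly equal
to mu returns t = 0, p = 1 (mirroring the paired t on identical vectors);
zero variance around any other mean is an error.

## Synthetic cohorts: what they emulate, and what they do not

Per participant, the generator draws (all units px unless noted):

| quantity | default | note |
|---|---|---|
| performance SD | N(40, 10), floor 5 | spread of true stops around the target |
| self exaggeration | N(0.6, 0.1), floor 0.05 | self prior SD = ratio x performance SD (< 1: optimistic) |
| agent prior | flat with p = 0.25, else N(1.0, 0.15) x performance SD | flat = SD 1e9 |
| evidence SD (agent) | N(30, 8), floor 10 | visual noise about the outcome; the floor sits near the 14-px-per-refresh stimulus granularity |
| evidence SD (self) | 0.85 x agent | multisensory advantage when acting |
| optimism (LOT-R) | 0-24 integer | built from the log-exaggeration residual after regressing out performance SD, mixed with noise to hit a target partial correlation (-0.5) |
| feedback factors | perf 0.8, evidence 0.75 | applied in during/after phases; prior SD never rescaled |
| momentum shift | N(18, 4); self = 0.6 x | directional report shift in no-target tasks |

The exp2/exp3 default cohorts draw matched agent priors without the flat
mode: those samples' reported uncertainty effects on the agent weighting
presuppose observation priors in every participant.

Timing fields are log-normal (estimation ~ LN(ln 1.4, 0.2) s, reaction
~ LN(ln 0.35, 0.22) s) with 2% slow outliers at 3-5x, purely so the 2-SD
exclusion rules have something to exercise — no claim about real reaction-
time distributions is intended. Agent replay permutes the self block's stop
positions, clamps them to the self mean +-2 SD ("truncation" read as
bounding, not redrawing), redraws sweep counts from {1..4}, and regenerates
reports from the agent parameters. One root seed per session; participant/
block streams are derived by hashing stable keys into a SeedSequence spawn
key, so cohort composition never perturbs an individual's data.

What passing tests therefore show: the estimation machinery recovers the
parameters of *this* generative process — Gaussian errors, exact
posterior-mode reporting, stationary parameters within phase — at the
study's trial counts. They do not show robustness to non-Gaussian motor
error, lapses, sequential effects, learning within blocks, or reports that
mix strategies, none of which the generator emulates.

## Problem sizes and numerical choices

Default experiment runs use 2 blocks x 52 trials per phase and condition
(experiment 1, 20 participants), 4-8 blocks of 48/32 trials (experiment 2,
10 participants), and 3 blocks x 40 trials per target (experiment 3, 6
participants). The statistical property suites use 200 trials/condition for
recovery and coverage (200 datasets at B = 500), 1000 cohorts for the
type-I simulation, and n = 10^4 trials for the identity checks. Model fits
pool phases except where feedback effects on the fitted SDs are themselves
the question, which uses per-phase fits. The qualitative checklist flags
positive findings at p < 0.05 and flags the prior-stability *null* claim as
broken only at the stricter 1% level, since a null restated as "p > 0.05"
would fail in one run out of twenty by construction.

## Known limitations

* Near-flat priors are weakly identified; their fitted SDs are reported as
  found (or at the boundary) and handled by classification, not by
  regularisation.
* The Spearman partial correlation ranks-then-residualises; other software
  residualises first. Differences are tiny but nonzero.
* The bootstrap's percentile intervals slightly undercover for scale
  parameters at n ~ 200 (measured ~0.90 for a nominal 0.95).
* Exclusion cells pool blocks within participant x condition x task; the
  alternative per-block reading would flag slightly different trials.
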