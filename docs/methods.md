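# Methods

## The behavioral step model

The engine's per-participant model treats each day as a two-regime
mixture. Conditional on the assigned goal `g`, baseline `b`, and the
momentum state `m` (the fraction of goals attained over the trailing
seven observed days, 0.5 before any history exists), the day is
*engaged* with probability

    π = logistic(κ₀ − κ₁·e + κ₂·m),   e = max((g − b)/b, 0)

and the step total is drawn from a Normal truncated to [0, ∞):
`N(max(g, b), σ²)` on engaged days, `N(b·(1 − ρ·e), σ²)` on discouraged
days. The structure encodes four behavioral claims: goals matter
(engaged days rise to the goal), over-ambitious goals backfire twice
(through κ₁ in the engagement odds and through ρ in the discouraged
mean), success breeds success (κ₂ > 0 makes recent attainment raise
future engagement), and a day's count is noisy but never negative.

Parameters, units, and estimation bounds:

| parameter | meaning                                   | bounds        |
|-----------|-------------------------------------------|---------------|
| `b`       | baseline steps/day                        | [500, 30000]  |
| `σ`       | day-to-day SD, steps/day                  | [100, 10000]  |
| `κ₀`      | engagement intercept (log-odds)           | [−5, 5]       |
| `κ₁`      | difficulty sensitivity, per unit `e`      | [0, 10]       |
| `κ₂`      | momentum weight, per unit `m`             | [0, 10]       |
| `ρ`       | fractional baseline loss per unit `e`     | [0, 1]        |

**Fitting.** Maximum likelihood over all observed days; the day
log-density is the two-component truncated-normal mixture (each
component renormalized on [0, ∞)), with momentum precomputed from the
trailing attainment record. Optimization is L-BFGS-B inside the box
bounds from 8 Latin-hypercube starting points (one start replaced by
method-of-moments values: mean/SD of observed steps), objective
tolerance 1e-6; the multistart draw is seeded from the study seed and
the participant id, so refits are deterministic. At least 14 observed
days are required. The multistart can occasionally settle ~1 log-lik
unit short of the global optimum, which disturbs `σ` more than `b`;
recovery contracts are therefore stated on medians across replicate
histories (observed: median relative error ≈ 3–4% for `b`, ≈ 7% for `σ`
on 70-day histories at the default truth).

## The weekly planner

Goals for the coming week maximize `Σₜ E[steps | gₜ, mₜ]` over the goal
grid (multiples of 500 in [2000, 20000] by default), with momentum
propagated by its certainty-equivalent update
`mₜ₊₁ = (6·mₜ + π(gₜ, mₜ))/7`, snapped to the nearest multiple of 1/7.
Backward dynamic programming over the 8-state momentum grid × goal grid
is exact for this objective (verified against exhaustive enumeration);
ties break toward the lower goal, and grid snapping rounds half up.

Two degeneracies are worth knowing. When the fitted `κ₁` and `ρ` are
both ~0 (ambition costless), the objective is nondecreasing in every
goal and the plan saturates at the grid maximum — this happens early in
a trial, when the participant has only seen easy goals and difficulty
response is unidentified; a week of failures then identifies it and
plans moderate. Conversely, when no goal above the baseline ever pays,
all goals `≤ b` predict exactly `b` and the lower-goal tie-break yields
the grid minimum. Both are consequences of planning greedily on a
point-estimated model; an exploration bonus or posterior sampling is a
natural extension point.

If a participant has fewer than 14 observed days, or the fit fails, the
engine falls back to a ramp of +250 steps/day from the trailing-7-day
observed mean (clipped to the grid) — the same engagement-building shape
as the run-in ramp.

## The simulator

`simulate_trial` emulates the full two-arm flow: identical run-in ramp
goals for everyone (days 1–7), independent 50/50 arm assignment
afterwards (so arm sizes differ by chance; `balanced_arms` forces an
exact split for calibration studies), control arm on the constant
10,000-step rule, intervention arm refit weekly by the engine. Each
participant consumes an independent RNG substream keyed by (seed,
index), so adding participants never perturbs existing trajectories,
and every output is a deterministic function of the seed.

Cohort heterogeneity comes from truncated-normal priors. The defaults
center `b` at 7300 steps/day with SD 2850, chosen so that simulated
run-in daily steps average ≈ 7300 with a between-participant SD ≈ 2900
(`sd(run-in mean) ≈ sqrt(sd_b² + σ²/7)` with the σ prior centered at
1500) — the scale typical of adult workplace step-goal cohorts. The
κ/ρ priors (κ₀ ~ 0.5 ± 0.5, κ₁ ~ 2.0 ± 0.8, κ₂ ~ 1.0 ± 0.5,
ρ ~ 0.3 ± 0.1, all truncated) give interior one-day optima for most
draws and a gradual decline of control-arm steps as momentum erodes
under a fixed 10,000-step goal.

App-nonuse missingness: on any active day an off-run starts with
probability `q` (default 0.05) and lasts Geometric(1/L) days (default
mean L = 4), giving a stationary missing fraction `qL/(1 + q(L−1))`
≈ 17% and roughly half the cohort with at least one ≥ 7-day off-run
over 10 weeks. Missingness is independent of steps (ignorable), matching
the likelihood analysis's assumption; off-day masks are drawn up front
so the engine and the percentile rule only ever see observed days,
while the participant's own (latent) momentum uses all days walked.

**What the generator does not emulate:** day-of-week and seasonal
periodicity, weather, wear-location artifacts, notification-timing
effects, informative (engagement-linked) missingness, and any natural
drift of baseline activity. Passing calibration and recovery tests on
these synthetic trials therefore demonstrates the pipeline's internal
correctness, not robustness to those real-world features.

## The analysis pipeline

**Steps model.** REML linear mixed model on observed daily steps with
time in weeks (`t = study_day/7`), a piecewise slope with the knot at
the run-in boundary (day 7 — the only structurally meaningful
breakpoint), fixed effects {intercept, pre-knot slope, post-knot slope,
arm, arm × post-knot slope}, and a random intercept and slope per
participant. The headline quantity is the end-of-study net between-arm
difference: interaction slope × post-knot duration (9 weeks in the
default design), with Wald 95% CIs. Missing days stay missing and are
handled by the likelihood; no imputation, and deliberately no
last-observation-carried-forward (it inflates late counts). If the full
random covariance fails, the model refits with a random intercept only
and records that in `notes`. A week-aggregated time coding is available
(`time_unit="week"`); there the pre-knot segment is a single point, so
that term drops from the fixed design.

**Attainment model.** Same fixed structure for the binary
attained/not-attained outcome. Default link is logit, fit as a Bayesian
binomial mixed GLM (variational approximation; its weakly informative
priors also regularize complete separation), random intercept and slope.
The net difference is reported on the probability scale as a
difference-in-differences of marginal attainment probabilities
(random effects integrated out by Gauss–Hermite quadrature) between the
run-in boundary and end of study, with a CI from sampling the
fixed-effect posterior; the variational optimizer's random start is
pinned so the fit is a deterministic function of the data. A
linear-probability LMM (`link="linear"`) is provided as a sensitivity
option whose interaction slope is already on the probability scale. A
constant outcome (everyone attains, or no one does) is reported as
degenerate rather than fit.

**Run-in adjustment.** Weekly means are raw per-arm means over observed
participant-days ("no imputation"); the run-in week's mean for each arm
is shifted by that arm's intercept offset from the mixed model (control
offset 0 under treatment coding), making the arms comparable at the
reference week. The adjustment is exactly invertible.

**Power and sample size.** Exact noncentral-t computation for the
two-sided two-sample t test. At the standard design point (Δ = 1500
steps, pooled SD 2000, α = .05) the smallest n reaching 80% power is 29
per group (the normal approximation gives 27.9); dividing by (1 −
attrition) and rounding up gives 33 at 10% attrition. Power at 30 per
group is 0.815.

**Operating characteristics** (recomputed by the test suite and
`scripts/acceptance.py`; sizes chosen to estimate each rate to a few
percent): type-I error of the interaction Wald test over 500
null-simulated trials at 20/arm (both arms on the control policy);
recovery of an injected linear divergence of 20 steps/day/day (net 1260
steps at week 10) over 100 replicate trials; baseline-parameter recovery
over 20 simulated 70-day histories; planner-vs-enumeration agreement
over 100 random 3-day, 5-goal instances. With ~500 replicates a
perfectly calibrated 5% test still reports rates roughly between 3% and
7%, and occasional seed streams fall outside that; the per-replicate
p-values are returned so calibration can be inspected directly.

## Numerical conventions

- Days are 1-based; week k is days 7(k−1)+1 … 7k; run-in = week 1.
- Missing steps are absent values (blank CSV cells), never 0.
- Attainment ties count as attained (steps = goal → attained).
- Percentiles are nearest-rank: the ceil(p/100·n)-th order statistic.
- Goal-grid snapping rounds half up; planner ties go to the lower goal.
- Momentum is snapped to multiples of 1/7 only inside the planner's
  state space; fitting uses the exact trailing fraction.
- Truncated-normal sampling and densities use the inverse-CDF and
  log-CDF forms (`ndtr`/`ndtri`/`log_ndtr`), stable far into the tails.
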