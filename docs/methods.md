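# Methods

## The game

Four players share a pool of points, initially 230. Each round every
player privately requests an integer harvest in [0, 20]; the pool is
reduced by the sum of fulfilled harvests and, if still positive,
replenished in two steps: an integer increment drawn uniformly between
`round(0.17·R_post)` and `round(0.23·R_post)` is added, and the result
is damped against the pool value at the start of the round,

    R_new = round(w·R_prev + (1 − w)·(R_post + increment)),   w = 1/3.

The game terminates when the pool reaches 0 (exhaustion) or after 109
rounds. The published description gives the 17–23% draw and the
one-third weighting separately but not their composition; the convex
combination above is this package's documented reading, exposed in
`EngineConfig` (`replenish_low_frac`, `replenish_high_frac`,
`previous_weight`) so an alternative composition can be swapped in.
All pool values are integers (the task displays integer points);
rounding is half-up. When requests exceed the remaining pool the
default fulfilment is proportional apportionment with
largest-remainder rounding (ties to lower player index); equal-split
water-filling and take-in-order fulfilment are selectable.

### Stability of the dynamics

With mean replenishment multiplier 1.20 the expected update under a
constant total harvest H is `R → R/3 + (2/3)(1.2)(R − H)`, with fixed
point `R* = 6H`. The map's slope is 1/3 + 0.8 = 17/15 > 1, so this
fixed point is *unstable*, and it is unstable for every admissible
configuration, since the slope `w + (1 − w)(1 + ρ̄)` exceeds 1 whenever
the mean replenishment fraction ρ̄ is positive. Simulated
constant-harvest chains started at R* = 120 leave it within a few
dozen trials and either exhaust (time-averages around 85–95) or grow
without bound; the engine therefore carries exact big-integer
arithmetic so even divergent trajectories simulate correctly. Nothing
pathological happens in actual games: harvests respond to the pool, and
above R ≈ 480 the 4 × 20 harvest cap cannot match ~13% net growth, so
bounded play requires the behavioral feedback described below. The
expected-update fixed point itself is verified by a Monte-Carlo probe
(one replenished update at R = 120, H = 20 averages back to 120).

## Environments and confederates

A game is 5 warm-up trials followed by eight 13-trial blocks: two
repetitions each of one-overharvester, two-overharvesters,
one-underharvester and two-underharvesters environments, in a rejection-
sampled pseudorandom order in which one-over blocks are never adjacent
to two-over blocks and one-under never adjacent to two-under.

The original confederate harvest schedules are not published, so role
levels are calibrated against the engine's expected dynamics. The
total harvest holding the pool flat is `R·ρ̄/(1 + ρ̄)` (= R/6 at the
defaults); each extra harvested point moves the expected pool by
`−(1 − w)(1 + ρ̄)` (= −0.8) points. Warm-up confederates split the
whole flat-pool budget three ways (the scripted partners alone hold
the pool near its start). In the main environments each confederate's
baseline is the four-player fair share R/24 — leaving the
participant's share available — plus a role offset that imposes a
target drift, by default −7 pool points per trial for an
overharvester, +7 for an underharvester and −1 ("gentle downward
pressure") for non-salient confederates, scaled with the current pool
and jittered by ±1 point. Pool-growing offsets fade out linearly as
the pool approaches 1.5× its initial value, reflecting that
under-harvesting raised the pool early in a game but sustained it
later — and preventing the structurally explosive regime above.

A note on calibration semantics: a lone harvester cannot impose
negative expected drift on any pool above ~83 points (the drift
`(2/15)R − 0.8h` is positive for all h ≤ 20), so "overharvesting"
is necessarily defined relative to the group's sustaining budget, not
in single-player isolation. Directional behavior is validated at the
block level: over 13-trial confederate-only simulations the pool
reliably falls in over-environments, rises in under-environments, and
stays within ±10% of its start during warm-ups.

## Social norms and rank

Each round's four fulfilled harvests define the descriptive norm: a
beta distribution on harvests rescaled to [0, 1], fitted by method of
moments with the population (n-divisor) variance —

    t = m(1 − m)/v − 1,   α = m·t,   β = (1 − m)·t

— which is closed-form, stable at n = 4, and preserves the sample mean
exactly. Feasibility is judged on the raw rescaled values; boundary
harvests (0 or 20) are clipped to [1e−3, 1 − 1e−3] before solving so
they cannot break the moment equations. Samples with zero variance or
infeasible moments (v ≥ m(1 − m)) are flagged degenerate, and rank
queries fall back to the midrank convention
`(#smaller + 0.5·#equal)/4`. A player's *relative rank* is the fitted
CDF at their own harvest (own harvest included in the fit, matching
the task's display of all four harvests); the regression uses rank,
rank² and rank³.

## Synthetic participants

No generative participant model exists for the original task; this
package's agents are the synthetic stand-in that gives the pipeline a
known ground truth. The harvest adjustment is

    ΔHarvest = a + b·Harvest_prev + c·Resource + d·OverPresent
             + e₁·Rank + e₂·Rank² + e₃·Rank³ + N(0, σ²),

with the request `round(Harvest_prev + ΔHarvest)` clipped to [0, 20]
(round first, then clip). Gaussian noise is used because it matches
the linear model fitted downstream. On a game's first trial there is
no previous harvest; the participant requests the four-player fair
share plus policy noise.

Default parameter sets were calibrated by simulation to reproduce the
qualitative published contrast, not any printed coefficient values
(those are standardized estimates on human data):

| parameter            | T+ (control) | T– (depleted) |
|----------------------|-------------:|--------------:|
| intercept            |          2.0 |           1.0 |
| previous harvest     |        −0.70 |         −0.35 |
| pool value           |        0.035 |         0.012 |
| overharvester present|          1.0 |           1.2 |
| rank, rank², rank³   | −18, 36, −24 |     −2, 4, −3 |
| noise sd (points)    |          2.0 |           2.0 |

The T+ set self-corrects strongly and follows the norm (its cubic rank
response is steepest at the extremes of the rank scale, so the largest
upward/downward adjustments occur when the last harvest ranked at the
bottom/top); its pool-value coefficient is large enough that T+ agents
approach the harvest cap on rich pools, which is what keeps realized
games bounded. The T– set is aggressive and norm-insensitive. At
cohort scale (400 games per group) the defaults give ~90% exhaustion
in T– versus ~13% in T+, with T– accumulating roughly 100 fewer points
per game on average; the T– exhaustion rate deliberately overshoots
the 50% observed in humans so that the direction of the group contrast
is unambiguous under simulation noise, and simulated T+ games run
about 95–105 trials while T– games end near trial 70.

## Regression models

Model 1 regresses ΔHarvest on the previous harvest, the current pool
value and an overharvester-present indicator (underharvesters/none as
referent), each with a depleted-treatment interaction (control as
referent). Model 2 keeps the structural main effects (without their
treatment interactions), and adds the rank polynomial and its
treatment interactions. First-trial rows are excluded, as are rows
where the pool ran short and truncated the request — there the
recorded harvest is censored by the environment rather than chosen,
and pilot simulations showed such rows bias the pool coefficient.
ΔHarvest is computed across environment-block boundaries (blocks do
not reset the series). No multiple-testing correction is applied;
each coefficient is judged at α = .05.

Estimation is pooled OLS (the published analysis reports pooled
observation counts), with participant-level cluster-robust standard
errors. The 95% confidence intervals come from a cluster bootstrap
that resamples whole participants with replacement. The default
interval is **bootstrap-t**: each resample's estimate is studentized
by its own cluster-robust SE and the t-quantiles are applied to the
full-sample SE. With 16 clusters per group the plain percentile
interval undercovers noticeably (~0.87–0.90 observed per-coefficient
coverage in pilot replications versus ~0.93–0.97 for bootstrap-t);
the percentile interval remains available via
`ci_method="percentile"`. Intervals are widened, when necessary, to
include the full-sample point estimate. Coefficients are reported
raw and standardized side by side (the response and every non-binary
regressor z-scored), since the printed reference table is labeled
standardized while its rank-polynomial entries are plausibly raw
scale.

### Parameter recovery

The recovery study (`parameter_recovery_study`) simulates 50
independent 16-per-group cohorts, refits Model 2 with 500 bootstrap
replicates, and counts how often each generating coefficient lies in
its 95% CI. Its cohort (`recovery_cohort_spec`) differs from the
default cohort in two deliberate ways: the groups share the structural
coefficients, because Model 2 omits structural-by-treatment
interactions and would otherwise be misspecified for the generator;
and harvests are kept interior to (0, 20), because boundary clipping
censors the response. Residual small-sample bias from the dynamic
feedback (harvests move the pool that later re-enters as a regressor)
is below ~0.4 sampling SDs per coefficient; observed coverage is
0.90–1.00 per term, fluctuating with binomial noise at 50
replications.

## Outcome statistics

Per game: the participant's total points, final pool value, exhaustion
flag and trials completed. Group summaries report means with standard
errors (flagged undefined for single-game groups). The exhaustion ×
treatment table uses the uncorrected Pearson chi-square
`N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))` with df = 1 — the published
statistic for the 8/16-vs-2/16 split, 5.24, is only consistent with
the uncorrected form (Yates correction would give ≈ 3.66) — and the
statistic is refused when a margin is zero.

## Reproducibility

Every stochastic component takes a seeded NumPy generator; cohorts
spawn per-game child seeds from a master `SeedSequence`, so runs are
bit-reproducible given a config. `run_full_analysis` writes a manifest
with the config hash, seeds, package version, row counts and SHA-256
checksums of every output file. Identical configs produce identical
checksums.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis assumes —
rank-driven cubic adjustments, treatment-dependent parameters, the
block environment design, pool exhaustion dynamics — so green tests
demonstrate that the pipeline recovers known parameters and directions
from data of that structure at realistic sample sizes. They do not
validate the behavioral claims themselves: human harvesting is not
literally linear-Gaussian in these regressors, confederate schedules
in the original task were hand-scripted rather than calibrated, and
printed human-data coefficients are not reproducible from simulation.
Magnitudes of the synthetic treatment contrast (e.g. the exhaustion
rate) were chosen for directional clarity, not to match the human
rates.
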