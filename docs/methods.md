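# Methods

## Task model and conventions

Angles are in degrees, 0° rightward, counter-clockwise positive. The cw
rule maps a pre-cue at θ to the goal θ − 90°, the ccw rule to θ + 90°.
Times are milliseconds from trial start; all analysis windows are
half-open `[start, end)` so boundary spikes are never double-counted. The
go signal coincides with rule-cue onset.

A likelihood ratio k:(6−k) (ccw:cw instructed trials per 8-trial block)
carries an initial expected value per rule of `iEV = k/8 + 1/8`: six of
the eight block trials are instructed and split k:(6−k), and the two
free-choice trials are worth half an expected unit to either rule. The
prior level is the normalized iEV difference
`|iEV_hi − iEV_lo| / (iEV_hi + iEV_lo)`, giving {0, 0.25, 0.5, 0.75}; this
reconstruction reproduces the canonical iEV table exactly. In the
zero-prior condition, follow/against congruency is undefined; cw reaches
are labelled *follow* by convention (presentation only).

Analysis windows: baseline `[−300, 0)` before pre-cue onset, pre-cue
`[0, 300)` after pre-cue onset, planning `[−300, 0)` before rule-cue
onset, movement `[movement_on, movement_off)`.

## Synthetic data generator

The generator defines the study conditions every stage is validated
against. It emulates, per subject (two by default, so subject-level code
paths are exercised), one session with `n_blocks = 84` successful blocks —
exactly three repetitions of each of the 28 ratio × location combinations,
a balanced design sized so that each prior-level × prior-direction cell
holds ≈ 36 trials per unit and population null tests are well powered —
and `n_units_per_area = 48` units across PMd and PRR (mixture 30% UR,
30% DR, 40% untuned).

Behavior: free choices follow the higher prior with logistic probability
`σ(2.8 · level)` (≈ 0.89 at level 0.75); instructed error rates are
`0.05 ± 0.25 · level` (clipped) for against/follow instructions; RTs are
log-normal around `420 ± 60 · level` ms (σ_log = 0.12), capped at the
800 ms response deadline.

Neural model: each tuned unit has a baseline (6–14 Hz), a response lobe
gain (16–30 Hz), and a von-Mises-shaped lobe `(e^{κ(cos δ −1)} − e^{−κ}) /
(1 − e^{−κ})` clipped at zero (κ = 4), which is exactly zero at and beyond
±90° — so conditions whose goals are orthogonal to a unit's preferred axis
carry literally no prior modulation, making "no Orth modulation" a sharp
null. During planning, UR units carry a single lobe at the high-prior goal
scaled by `slope · level` (hence untuned at zero prior), while DR units
carry lobes at both potential goals with the devalued goal's lobe scaled
by `1 − slope · level` (choice-set co-encoding). Normalized modulation
slopes are drawn from 0.8–1.2 per unit prior level. Note that a normalized
slope of 2 per level is not representable with non-negative rates (the
full-prior response would require a negative baseline), so "strong
modulation" in the recovery studies means slopes near the feasible maximum
(~1.2). After rule-cue onset each unit transitions (logistic blend, 20 ms
time constant) to single-goal movement coding at its selection latency:
area base (PMd 160 ms, PRR 200 ms) + class offset (DR −15 ms, UR +15 ms) +
N(0, 5 ms) jitter — the PMd-DR-first ordering the latency stage must
recover. Spiking is inhomogeneous Poisson on a 1-ms grid (per-bin Poisson
counts, within-bin uniform jitter). A single root seed spawns named child
streams (units, trials, behavior, spikes).

What the generator does *not* emulate: trial-history effects, fixation
breaks/aborts, idiosyncratic non-linear per-subject bias shapes,
non-Poisson spiking variability, and within-session nonstationarity.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under these idealized conditions, not robustness to every property
of real recordings.

## Spike densities

The EPSP-like kernel is `(1 − e^{−t/τ_g}) e^{−t/τ_d}` for t ≥ 0 (τ_g = 2,
τ_d = 50 ms), normalized to unit area on its sampled support: the shape is
fully determined by the two time constants, and unit area is the natural
scale contract — it makes the integral of a density over an interval
estimate the expected spike count there. The Gaussian kernel (σ = 50 ms), also unit-area, is used for
every velocity/latency computation (symmetric kernels give more reliable
rate-of-change estimates). Spikes outside a requested window but within
kernel support contribute to the window (padded binning, no zero-padding
edge artifacts).

## Tuning and gating

The directional tuning vector is the rate-weighted sum of the four
cardinal unit vectors, computed from raw (not baseline-subtracted) epoch
means — the baseline-subtraction variant is a configuration choice, not a
default. PD_max ties are broken toward the continuous DTV angle.
Motor-goal neurons must exceed 5 Hz in at least one analysis epoch and be
Kruskal–Wallis selective (p < 0.01) for the reach goal during planning in
full-prior instructed trials, where the goal is announced by the pre-cue.
Degenerate all-equal inputs return p = 1; directions with fewer than two
trials gate the unit out rather than raising.

Continuous tuning curves use the standard even-N trigonometric
interpolant: mean + first harmonic + Nyquist cosine at half weight (the
Nyquist sine is unobservable at four samples). Interpolation is
presentation-layer only; every statistic runs on the four sampled
directions.

During planning the tuning coordinate is the *high-prior direction* (the
direction the larger arrowhead points to; cw-goal by convention at zero
prior), since the final goal is still unknown. Population tuning shifts
each unit's curve so PD_max → 0°, divides by the unit's full-prior PD_max
planning response, and averages across units.

## Prior modulation and UR/DR classes

Per unit, planning rates normalized by the full-prior PD_max anchor are
regressed on PRIOR (continuous level), PRIORDIR (high prior toward PD_max
vs OD, ±½ coding) and their interaction (OLS); marginal prior slopes per
role come from linear contrasts. Zero-prior trials whose goals span the
unit's PD axis anchor both regression lines (they are the shared
level-zero point of the two curves). The modulation angle is
`arctan2(max(s_PD, 0), max(−s_OD, 0))` — up-regulation on the y-axis,
down-regulation magnitude on the x-axis, wrong-sign slopes collapsing onto
an axis. Classification at α = 0.05 per slope requires the expected sign:
UR = significant positive PD slope and angle > π/4; DR = significant
negative OD slope and angle < π/4; both-significant units are labelled
`both` and excluded from the dichotomy.

### Dip statistic

The dip of a sample is the sup-norm distance from its empirical CDF to the
nearest unimodal distribution function (atoms permitted at the mode). The
implementation decides, for a candidate half-width d, whether a unimodal
CDF fits inside the band ECDF ± d: the rising (convex) flank is analysed
by a dynamic program that propagates the smallest admissible value and
slope forward through the per-point corridors (`[c_j/n − d, c_{j−1}/n + d]`
at the j-th unique value); the falling flank is the same computation on
the mirrored ECDF; the flanks must meet at a mode point with the left
flank's minimal end value not exceeding the right flank's maximal start
value. The statistic is located by bisection (60 iterations, ~1e-15).
The implementation agrees with an independent linear-programming oracle
(brute-force minimax fit per mode position) to < 2e-13 over thousands of
fuzz cases including heavily tied samples; canonical values: equal point
masses at two locations give exactly 1/4, a point mass gives 0, n evenly
spaced distinct values give 1/(2n). P-values are Monte-Carlo: the fraction
of uniform(0,1) samples of matched n with dip ≥ observed (default
N = 10,000, seeded; a precomputed null table can be shared across tests of
equal n).

### Population tests

The population-level PRIOR × PRIORDIR test defaults to a precisely defined
two-stage procedure — per-unit OLS prior slope within each role, then a
one-sample t-test across units per role — because no binomial/random-slope
GLMM implementation is part of the dependency set and two stages make the
result reproducible to the digit. A linear mixed model (per-unit random
PRIOR × PRIORDIR effects) is available via `method="mixed"` and falls
back, flagged, on failure. Post-hoc contrasts between successive prior
levels are paired t-tests across units, Bonferroni-corrected within each
role family. The same two-stage pattern serves the behavioral models
(per-subject GLM, inverse-variance pooling — the natural route with two
subjects) and the ROC suite's REACHDIR test.

## Latencies

ND(t) is the Euclidean norm across units of the difference between the two
opposing-goal condition-averaged, per-unit-normalized Gaussian densities,
averaged over the four pre-cue locations; no dimensionality reduction.
Velocity is a centered finite difference per ms; MVT is the earliest time
of maximal positive velocity in a 0–600 ms window after rule-cue onset
(the response deadline is 800 ms; the window is a declared default), with
ties resolved to the earliest bin under a 1e-9 relative tolerance so that
float rounding cannot hide a tie. PT is the first bin after MVT with
velocity below 0.3 (configurable; on per-unit-normalized densities this
canonical threshold is generous, so PT typically tracks MVT closely —
retained for comparability rather than as an independent estimate). Flat
or falling trajectories yield a no-latency flag instead of a number.
Bootstrap resamples *units* with replacement (N = 1000, percentile 90%
CIs); the permutation test reassigns units between areas at matched sample
sizes (N = 10,000) and scores the fraction of |MVT_A − MVT_B| at least as
large as observed. Cross-class latency comparisons default to the
zero-prior and one mid-prior condition, where both opposing-goal cells
hold enough trials.

## Choice prediction

Free-choice trials are sorted per unit into Prior-in/Prior-out/Orth (high
prior toward PD_max, OD, or orthogonal; zero-prior trials get a neutral
label excluded from between-prior ROCs) and Reach-in/Reach-out. AUCs are
rank-based with ties at ½ and require ≥ 5 trials per class (configurable).
Signal correlations are Pearson coefficients of planning rates across
trials pooled within each prior level, for simultaneously recorded pairs,
with PD distance folded to {0°, 90°, 180°}; the prior trend of
opposite-PD anti-correlation is tested two-stage across pairs.

## Pipeline report

The end-of-run report asserts six population slope checks (UR: positive
PD slope, null OD, null Orth; DR: negative OD slope, null PD, null Orth)
as one Bonferroni family (α = 0.05/6), plus angle-distribution bimodality
per area and the PMd-DR-first MVT ordering. With the default balanced
design these assertions are stable across seeds; the Bonferroni family
keeps the false-alarm rate of the null assertions at the nominal α.

## Numerical and degenerate-input choices

- Epoch rates use half-open windows; a spike exactly on a window end never
  counts.
- CSV interchange writes floats with `%.17g` and reads with pandas
  round-trip precision, so a written bundle reproduces the in-memory
  bundle bit-exactly (verified by digest in the pipeline tests).
- All-equal Kruskal–Wallis inputs → p = 1; all-zero direction means → DTV
  flagged angle-undefined; units without a positive normalization anchor
  are dropped with a count.
- Every stochastic stage takes an explicit `numpy.random.Generator`; the
  pipeline derives stage streams from the root seed via `SeedSequence`
  spawning.

## Problem sizes

Default test and acceptance runs use: 96 units / 1344 trials (pipeline),
200 units for class recovery, 100 units per population × 20
trials/condition for latency studies, 2000 uniform replicates for dip
calibration, and 2000 free-choice trials for behavior-model power — sizes
chosen so each check is decisively powered under the generator's effect
sizes.
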