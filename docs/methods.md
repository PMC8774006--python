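# Methods

This note documents the models, parameters and design decisions behind
`nftrial`: what the synthetic generator emulates, how each analysis
stage is defined numerically, and what the passing test suite does and
does not establish about real data.

## Trial design and randomization

The emulated design is a three-arm (CT-NF / CT / ACT), 1:1:1,
sex-stratified randomized trial of 60 young adults (20–30 y), training
~20 min/day over a 28-day window with mean adherence ≈ 25 days.
`assign_groups` uses permuted blocks within each sex stratum. The
default block length is 3 (one slot per arm), which makes the stated
1:1:1 allocation exact for stratum sizes divisible by 3. A block
length that is not a multiple of the number of arms (e.g. 4, which
cannot hold three arms equally) is supported through a balanced-urn
scheme: blocks are cut from a stream of whole permuted arm sets and
re-shuffled, so every released block has the configured length and
exact balance returns every lcm(block, arms) allocations.

## Cohort generator

Baseline scores are truncated normals at the published per-arm means
and SDs, truncated at instrument bounds (digit span forward ≤ 9,
backward ≤ 8, logical memory ≤ 25 story units, mental rotation ≤ 48,
reading screen ≤ 25, all scores ≥ 0) by resampling rather than
clipping, so no point mass accumulates at the bounds and the draws
follow the exact truncated-normal law (verified against the
closed-form expectation). Ages default to uniform integers on
[20, 30]; `age_mode="normal"` reproduces the published per-arm age
distributions instead.

Change scores are drawn per arm and outcome as Normal(mean, sd) with
the published parameters and added to baseline. **Post scores are not
re-truncated at instrument ceilings by default**: backward digit span
(baseline ≈ 6.0, change ≈ +1.55, ceiling 8) and delayed logical memory
sit close enough to their ceilings that enforcing them would shift the
realized change means by ~0.5 — incompatible with treating the
published change distributions as the generator's calibration targets.
`truncate_post=True` restores bounded post scores for users who need
them; the realized change means are then biased low near ceilings,
which mirrors the measurement compression a real ceiling would cause.

### Brain–behavior coupling

In the CT-NF arm, a shared standard-normal latent factor links the NIRS
activation change (both hemispheres) to the coupled cognitive outcomes
(delayed logical memory, backward digit span, digit cancellation —
the outcomes reported as neurofeedback-responsive). Each coupled
variable is `mean + sd·(√c·z + √(1−c)·ε)`, so every marginal stays
exactly Normal(mean, sd) while any two coupled variables correlate at
`c`. The default coupling c = 0.3 reproduces standardized regression
coefficients of ≈ 0.26–0.33 for NIRS-on-cognition regressions at
n = 20, the published order of magnitude. Coupling 0 gives exact
independence; coupling 1 makes the NIRS change an affine function of
the cognitive change.

Missingness is MCAR on post-score cells only (default rate 0.05).
The published report gives intention-to-treat imputation but no
dropout mechanism, so nothing more structured is attempted; MAR/MNAR
dropout is out of scope.

## Raw session generator

One session is `n_cycles` = 13 cycles of 30 s rest + 60 s task
(19.5 min) sampled at 10 Hz (the device's rate is unpublished; both
are configurable). Four channels are produced per session. The long
channels contain:

- linear drift with a random slope (SD 2×10⁻⁴ a.u./s);
- systemic oscillations: a Mayer-wave component (random frequency in
  0.08–0.12 Hz, amplitude 0.04 a.u.) and a cardiac component
  (1.0–1.3 Hz, amplitude 0.015 a.u.);
- sparse motion spikes (Poisson 0.5/min, Laplace amplitudes of scale
  0.08 a.u., 0.5 s exponential decay);
- the neural term: a task boxcar convolved with a unit-area gamma
  kernel (shape 4, scale 2 s → mode 6 s), amplitude set by the arm and
  day (below);
- white noise (SD 0.02 a.u.).

The short channels carry the *identical* drift/systemic/motion
realization scaled by a partial-volume factor (0.7) plus independent
white noise and no neural term — exactly the structure the dual
source-detector regression assumes. Amplitudes are in the device's
arbitrary ΔtotalHb units, scaled so that the feedback clamp ceiling of
0.2 is attainable in late training.

### Neural amplitude schedule and calibration

CT and ACT hold a constant task amplitude of 0.05 a.u. every day.
CT-NF ramps linearly from 0.05 on day 1 to a per-hemisphere ceiling on
day 28, multiplied by a per-participant gain ~ Normal(1, 0.35)
(resampled positive) shared across sessions and hemispheres.

The ceilings (left 0.359, right 0.304) are calibrated — once, as part
of the generator's definition — so that the *full offline chain*
recovers mean activation changes of 0.17 (left) and 0.14 (right) a.u.
in the CT-NF arm, the published group means. Calibration is needed
because the chain does not return the raw amplitude: with 30/60 s
blocks and a 6-s-lag hemodynamic kernel the measured task mean loses
the rise time (≈ m/task_s with kernel mean m ≈ 8 s) and the preceding
rest mean gains the carry-over of the previous task's decay
(≈ m/rest_s), plus ≈ 5% filter edge smear — a net recovery factor of
≈ 0.60. Combined with the ≈ 0.91 first/last-3-day ramp separation at
~25 trained days, the change per unit ramp is ≈ 0.55, giving the
ceilings above. The participant gain SD of 0.35 reproduces the
published between-subject change SD (~0.06 a.u. left).

The same mechanics mean the chain's "recover a known amplitude"
property only holds near steady state: the test suite verifies ≤ 5%
error with long blocks (60 s rest / 120 s task) and a fast kernel,
and the default-geometry recovery factor is the documented 0.60, not
1. At the default geometry the residual loss floor (filter edge smear
alone, no hemodynamics) is ≈ 5.2%.

## Neurofeedback engine

The fed-back signal is the mean of the two raw long channels; no
short-channel correction is applied in real time (the published
computation uses the average total Hb directly). Feedback updates at
1 Hz (cadence unpublished). Each value is the mean over the trailing
5 s window (all available samples during the first 5 s of a block)
minus the full preceding-rest mean, clamped to [0, 0.2]. Values map
linearly to RGB from blue (0, 0, 255) through purple to red
(255, 0, 0), rounding half-up. The session score is the mean of all
update ticks across all task blocks, rescaled to 0–100 and reported to
one decimal. CT and ACT sessions run the identical computation for
logging symmetry but emit a constant color.

## Offline preprocessing

Order of operations: linear detrend → zero-phase low-pass →
per-session OLS of long on short (residual = neural estimate) →
rest-baseline correction of each task block → mean over task samples.
The filter is a 4th-order Butterworth at 0.1 Hz applied
forward–backward over the full session (blocks are extracted
afterwards, avoiding per-block transients); only the cutoff is given
in the source description, the order and zero-phase application are
this package's choices. The exact published dual-SD algorithm is not
public; per-session OLS with intercept is used, and a degenerate
(zero-variance) short channel falls back to the unmodified long
channel with a warning. The activation change is the mean over the
last three *recorded* training days minus the first three (adherence
< 100% means calendar days and training days differ); at least six
valid days are required.

## Inference

- **Permutation ANCOVA** (the confirmatory test): F for the group
  factor from `change ~ group + pre + age + sex` versus the
  covariates-only model; η² = SS_group/SS_total. The null distribution
  follows the Freedman–Lane scheme — permute the reduced-model
  residuals, add back the reduced fit, recompute F — with a fixed
  permutation count (default B = 5,000; B = 1,000 in large calibration
  loops) rather than the sequential stopping rule of the original
  software, trading a little speed for exact seed-reproducibility.
  p = (1 + #{F* ≥ F})/(1 + B), so p values live on the k/(B+1) grid
  and are never 0. Sex enters as a single indicator, age centered.
- **Post-hoc contrasts**: the same test restricted to each arm pair,
  Bonferroni-multiplied by 3 and capped at 1.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels) with the eight
  cognitive outcomes as one family and the two hemisphere outcomes as
  a second family.
- **Brain–behavior regression**: all variables standardized, OLS of
  NIRS change on cognitive change plus covariates; the focal
  coefficient is reported as standardized β with its t, and the
  two-sided permutation p permutes the covariates-only residuals of
  the outcome (Freedman–Lane on the focal predictor).
- **Multiple imputation**: chained-equation predictive mean matching
  (m = 20, 5 donors, 10 iterations): each missing cell is filled with
  an observed value of its column borrowed from one of the k donors
  with the closest OLS-predicted mean (type-0 PMM; regression
  parameters are not redrawn per imputation — the m chains differ
  through their random initialization and donor draws). The sampler
  is implemented in-package and property-tested (observed-support
  membership, determinism, hand-computed nearest-donor
  toy). Per-imputation
  permutation results are pooled by **medians** (of p, F, η²); Rubin's
  rules do not apply to permutation p values, and the rule is recorded
  in the result metadata.
- **Power**: noncentral-F power for the group test with
  df₁ = arms − 1, df₂ = N − arms − covariates, λ = f²·N, converting
  the planned pairwise effect d to Cohen's f as f = d/2 (the
  two-extreme-groups convention; the conversion the original
  calculation used is not stated). With d = 0.79, α = 0.05, power
  0.80 and three covariates this yields N = 65 (66 balanced) — close
  to, but not exactly, the 60 the original calculation reported,
  which is why the package reports the computation rather than the
  constant.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations as
follows: generator mean-recovery at n = 100,000 draws; type-I-error
calibration over 1,000 null trials of n = 60 with B ≈ 500–1,000;
exhaustive-enumeration agreement on n = 7–8 toys; the NIRS pipeline
recovery over 200 simulated participants at full session resolution;
and effect-detection consistency over 200 simulated trials at the
published effect sizes. A full default-scale `run_trial` (60
participants × ~25 sessions at 10 Hz, m = 20 imputations) completes in
a few minutes on one CPU.

## What the synthetic validation does not show

The generator realizes the *published summary statistics* plus
explicitly stated structural assumptions (Gaussian changes, MCAR
dropout, linear amplitude ramp, shared-scaled scalp physiology, one
latent coupling factor). Passing tests therefore demonstrate that the
pipeline is correct and calibrated under those assumptions — not that
the assumptions hold for real NIRS recordings, which feature
non-Gaussian motion artifacts, serially dependent physiology,
habituation, non-linear learning curves and structured dropout. The
original trial's participant-level results (specific F statistics,
post-hoc p values, regression coefficients) are not reproducible
without the undeposited data and are not claimed.
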