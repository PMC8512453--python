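# Methods

This note documents the models, conventions and numerical choices behind
wearval, in the order the pipeline runs.

## Synthetic cohorts and protocols

`make_subject` draws children with ages from a normal distribution
(mean 9.7 y, SD 1.9) truncated to [7, 13]; the pre-truncation location is
solved numerically (Brent's method on the truncated-normal mean) so the
*post*-truncation mean equals 9.7 exactly. Height is age-linked
(138.3 cm at the mean age, 5.8 cm/y slope, 6.5 cm residual SD) and weight
follows from a BMI draw (mean 16.3, SD 2.7, floored at 12), so all
covariates have positive support and match a typical elementary-school
cohort. One global integer seed drives every stochastic stream through
`split_rng(seed, *labels)`, which spawns a `numpy` generator keyed by the
CRC32 of each label (e.g. `("gas", subject_id)`); streams are therefore
independent, reproducible, and re-runnable per module.

The default lab protocol is a 50-min session: 3-min inclined rest, then 14
activity stations each preceded by a 1-min transition (2.0 MET, walking
between stations). Station MET targets are compendium-style values
(1.3–7.3) spanning sedentary through vigorous play; the two stations at
≤ 1.5 MET are category `sedentary`. Light stations last 3 min and MVPA
stations 2 min, which (a) totals exactly 50 min and (b) keeps every
segment a whole number of minutes so 60-s epochs align with segment
boundaries — the property that makes noiseless round trips exact rather
than approximate. Station values deliberately avoid sitting exactly on the
3.0 and 6.0 MET class boundaries, where any measurement noise would flip
classifications.

## Gas-exchange simulation

Each breath row carries the *mean* metabolic rate over the interval since
the previous breath (backward-interval convention), with the last breath
of each segment placed exactly at the segment end so intervals never
straddle segments. The underlying MET trajectory follows segment targets
through first-order on-kinetics with time constant τ (default 20 s, a
typical pediatric VO₂ response time); the per-interval mean and exit state
are computed analytically, so τ → 0 reduces exactly to the step target.
VO₂ = MET × resting VO₂/kg × weight, with resting VO₂/kg defaulting to
5.0 mL·kg⁻¹·min⁻¹ — children's resting uptake is well above the 3.5 adult
convention, which is why the lab arm individualizes the 1-MET baseline
instead of assuming a constant. Multiplicative noise is lognormal with
unit mean and coefficient of variation `vo2_noise_cv` (default 0.10,
typical breath-to-breath variability). Breath spacings are gamma-jittered
(shape 25) around a 2-s mean and rescaled to tile each segment. VCO₂ is
carried at a fixed RER of 0.85 but used by no computation.

## Epoch aggregation and the lab arm

`aggregate_breaths` integrates the breath step function over epochs
(overlap-weighted mean). A breath never covers more than 30 s back, so
recording gaps leave epochs NaN ("missing") — missing epochs are excluded
from every mean and sum, never imputed as zero. Epochs are assigned to the
protocol segment covering the majority of the epoch, ties to the earlier
segment. The 1-MET baseline is the mean VO₂/kg over epochs fully inside
the rest segment (all rest epochs are used; no acclimation discard). MET
bands are closed as SED ≤ 1.5 < LPA < 3.0 ≤ MPA < 6.0 ≤ VPA: the printed
anchors are preserved and the gaps of the discrete formulation (1.5–1.6,
5.9–6.0) are closed half-open so the classes partition the line. MVPA
excludes transition epochs; sedentary stations enter classification (they
classify SED) but are excluded, with rest and transitions, from AEE.

One unit-direction note: converting VO₂ from mL/min to L/min is a division
by 1000, although methods writeups in this literature occasionally state
it as a multiplication; the code divides, and a guard test pins the 1000×
inflation that the opposite choice would cause. The caloric
equivalent is fixed at 4.867 kcal per litre O₂; no Weir/RER substrate
partitioning is attempted. Schofield weight-only coefficients (kcal/day):
boys 22.7 W + 495 (3–10 y) / 17.5 W + 651 (10–18 y); girls 22.5 W + 499 /
12.2 W + 746. Net AEE may legitimately be negative (light sessions in
large children); it is flagged with a warning, never clamped.

## Acceleration simulation

Worn segments superimpose movement along a per-segment random gravity
direction: the per-sample excess magnitude is `e · (1 − cos 2πt)` with a
1 Hz fundamental, whose mean over any whole second is exactly `e`, the
MET-mapped ENMO target. The affine MET→ENMO map (slope 110.5 mg/MET,
intercept −19.7 mg at 1 MET, floored at 0) is anchored so that 1.5 MET maps
to 35.6 mg and 3.0 MET to 201.4 mg — the class boundaries of the two arms
agree by construction, which is a modeling convenience, not a physical
claim; only monotonicity is meaningful. Per-sample lognormal noise
(CV 0.25) models waveform irregularity. Non-wear segments are a constant
unit gravity vector plus per-axis uniform noise bounded by the 2-mg noise
floor. Samples are stored float32; all reductions run in float64.

## Free-living schedule

Each simulated day (whole-minute blocks): sleep 00:00–07:00 and
21:30–24:00, sedentary (1.3 MET ≈ 13.5 mg, a realistic quiet-sitting
level) and light (2.0 MET) filler, MVPA bouts at 4.0 MET at 09:00 and
13:00 totalling the programmed minutes (≤ 120/day), and a 100-min non-wear
bout at 16:00. Parents' logs record the sleep and non-wear intervals.
Daily wear is 770 min, comfortably above the 600-min retention minimum.
The device model applies a proportional bias plus additive Gaussian noise
to the programmed truth and floors at zero.

What the generator does *not* emulate: realistic gait spectra and
autocorrelated activity bouts, heart rate, GPS/altimeter channels,
device-specific filtering, temperature-dependent sensor drift, or
proprietary container formats. Passing round-trip tests therefore
demonstrate that the *processing chain* is correct and internally
consistent — not that the pipeline's accuracy on real children's data
equals its accuracy here.

## Calibration, ENMO, non-wear

Autocalibration collects 10-s windows whose per-axis SD is below 13 mg,
requires at least 3 distinct orientations (pairwise > 30°), and fits
per-axis gain and offset by iterated regression of raw window means onto
their unit-normalized calibrated versions — a simplified, temperature-free
version of the sphere-fit used by raw-accelerometry toolchains. Fits are
capped at 2000 windows (evenly spaced, preserving posture diversity);
gains outside (0.5, 2) or degenerate geometry return an identity model
flagged non-converged. ENMO truncates negatives per sample *before*
averaging (the operations do not commute: a 0.5 g/1.5 g mixture reads
250 mg, not 0). The Choi rule is defined on counts in its original form;
here "zero activity" means per-minute ENMO < 1 mg (configurable), with the
published 90/2/30-min parameters. Both the algorithmic non-wear mask and
the parent-log exclusions are applied; calendar days are midnight-bounded
and partial days obey the same wear minimum.

## Statistics

MAPE is computed per participant then averaged. Bias direction is an
explicit parameter everywhere (`criterion_minus_device` default for the
lab arm, `device_minus_criterion` for free-living, mirroring how such
tables are usually printed); the two directions are exact negatives.
Bland–Altman LoA use 1.96 SD of the paired differences; the bias 95 % CI
uses the t quantile, and "systematic bias" means that CI excludes zero.
The 90 % CI of device estimates is the two-sided t interval. The minimal
equivalence zone is reported at 0.1 % granularity and rounded *up*:
the reported zone must still contain the CI, which is the defining
property of the statistic (ceiling also reproduces the published
worked-example values, including one that nearest-rounding would miss).
Equivalence is closed inclusion of the CI in the zone bounds. Biases, LoA
and percent quantities are rounded to one decimal for reporting; full
precision is kept internally.

## Problem sizes and determinism

Validation runs default to 20 lab subjects and 5 free-living subjects ×
7 days at 30 Hz (≈ 18 M samples per subject-week, processed day-wise in
float32); the test suite uses the same designs with shorter wears or lower
rates where the property under test permits. Monte-Carlo checks use
10 000 replicates for CI coverage, 1000 sequences for the non-wear oracle
comparison, and 200 replicate sessions for gas-exchange recovery. All
randomness descends from one integer seed; reports serialize with sorted
keys and no timestamps, so a fixed config and seed give byte-identical
JSON.

## Known limitations

Single fixed caloric equivalent (no RER dependence); no sleep-stage
detection (sleep exclusion relies on logs and the non-wear rule); the
MET→ENMO map is affine by construction while real intensity–acceleration
relations are not; calibration omits temperature compensation; the device
model is a two-parameter black box and cannot reproduce intensity-specific
device errors.
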