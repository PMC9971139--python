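# Methods

This note documents the models, numerical choices and limitations behind
`fluokin`, in the order the pipeline runs.

## Synthetic exercise generator

The generator emulates a lidded grid-phantom search-and-remove exercise: a
4 × 7 grid (28 locations, 25 mm pitch, 8 mm lid radius) hides `n_targets = 3`
fluorescent targets per exercise, placed uniformly at random without
replacement. Target intensities are drawn uniformly from 1.0–3.5 (relative
units calibrated so a rendered-and-remeasured SBR equals the intensity;
an SBR of 1 is zero contrast), matching the range a dilution series of a
near-infrared dye produces under a fluorescence endoscope.

**Detection.** Whether the operator sees a target in fluorescence mode is a
Bernoulli draw with psychometric probability Φ((SBR − θ)/σ). Defaults
θ = 1.5, σ = 0.1: detection is near-certain two sigma above threshold and
near-impossible two sigma below, so degradation concentrates just under
SBR 1.5. θ is the quantity the cutoff analysis is later asked to recover; σ is
deliberately exposed because no per-target detection statistics exist to pin
it down.

**Movement.** Every lid-to-lid movement is a minimum-jerk reach, position
profile 10τ³ − 15τ⁴ + 6τ⁵ (the standard point-to-point motor-control model).
This choice is load-bearing: the profile has a closed-form jerk,
∫j²dt = 720·D²/T⁵, which makes the dexterity index analytically checkable.
A detected target triggers one direct reach; an undetected one triggers a
memoryless uniform random search over still-closed lids (excluding lids of
targets not yet searched for, so error attribution per target is exact), each
non-target opening logged as a handling error. Each detection attempt costs
`scan_time_s = 2 s` in fluorescence mode, and by default the operator
re-enters fluorescence mode before every candidate opening during search
(`refirefly_during_search`), so hard targets accumulate Firefly time; both
behaviours are configurable because real operators differ here. Reaches take
1 s, lid openings 0.5 s, sampling is 30 Hz (endoscopic video rate).

**Noise.** Additive Gaussian position noise (SD 0.5 mm, the scale of
video-tracking error) low-pass filtered at 6 Hz (4th-order Butterworth,
zero-phase) so it resembles tracking jitter rather than white noise. Noise
still dominates the third derivative of real-scale movements, which is
physically faithful: jerkiness in tracked data is largely measurement-driven,
and the dimensionless Dx ordering (longer, more hesitant exercises score
higher) is what carries information, not its absolute magnitude.

**What the generator does not emulate:** bimanual movement, occlusion gaps in
tracking, tissue optics/depth attenuation, operator learning across exercises,
and extreme-jerk tracking glitches. On the last point: at 30 Hz with a
smoothing differentiator, no plausible synthetic motion exceeds the literal
100 000 m/s³ extreme-peak threshold, so default cohorts have #J_extr = 0 and
that DM feature normalizes to zero weight. Passing tests on synthetic cohorts
therefore demonstrate the machinery (normalization, weighting, anchoring,
breakpoint recovery), not that real tracking data would yield the same weight
allocation.

**Rendering.** Fluorescence-mode frames place each target as a green
flat-top-core blob (core radius = half the lid radius, Gaussian skirt) with
peak green = background level × intensity over a dark background (green 40,
red/blue at 10%), so a small centre ROI measures SBR ≈ intensity; white-light
frames show grey lids on a bright background. Optional saturated white discs
emulate specular reflections for testing the saturation mask.

## SBR measurement

Near-white pixels (normalized HSV saturation < 0.15 and value > 0.9 — the
thresholds are a design choice, exposed as parameters) are masked as specular
reflections. Signal is the mean green channel over unmasked pixels of a
rectangular ROI at the target; background is the mean of three background-ROI
means. "Adjacent" background locations are operationalized as the three
nearest non-target lid centres (helper `propose_background_rois`); ROIs are
otherwise caller-supplied. Measurements are relative: camera distance and
exposure are not modelled, so SBRs are comparable within a recording setup
only. Marker segmentation (HSV range + connected components + rectangularity
filter + largest-area tie-break) and the monocular pinhole depth estimate are
simplified conveniences for video-derived tracks, not a calibrated stereo
tracking framework.

## Kinematic metrics

Derivatives use a Savitzky–Golay local-polynomial differentiator, default
window 7 samples, polynomial order 3, requiring near-uniform sampling. Third
derivatives amplify noise steeply, hence the smoothing window is a first-class
config knob. Edge samples take their derivative from the first/last full
window's polynomial (`mode="interp"`); no endpoint trimming by default, since a
minimum-jerk reach carries its largest jerk exactly at the endpoints and
trimming would bias the 720 oracle by tens of percent (an optional
`endpoint_trim` exists for noisy data). The jerk integral uses the trapezoid
rule; at 500 Hz sampling the dimensionless core of an ideal reach converges to
720 within 0.25 %, at 30 Hz it is biased low by ~30 % — consistent across a
cohort, so rankings and scores are unaffected.

Conventions chosen where several standard definitions exist: jerk magnitude is
the Euclidean norm of the 3D jerk vector (the 100 000 m/s³ peak threshold
applies to the norm; inside Dx the squared norm equals the per-axis sum of
squares); an extreme-jerk peak is a *strict* local maximum above threshold
(plateaus count zero; a 1e-9 relative epsilon suppresses float jitter on exact
plateaus); curvature is the discrete Menger (circumscribed-circle) curvature
averaged over consecutive triples, with collinear triples contributing 0;
angular dispersion is 1 − mean resultant length of unit step directions
(circular-statistics convention: 0 straight, →1 isotropic). Positions are
stored in mm and converted to metres for every derivative quantity, so the
jerk threshold applies literally. Mode times attribute each inter-sample
interval to its leading sample's mode; the position-density map does the same
per 10 mm XY bin and always sums to 100 %.

## Scoring stack

DM features are cohort min–max normalized before weighting: the raw features
mix counts and seconds, and unscaled mixing would make a fixed 0.02 weight
grid meaningless. (Unnormalized behaviour is selectable with
`normalize=False` for sensitivity analysis.) A cohort-constant feature
normalizes to zero. The weight search is exhaustive over the 0.02-step
simplex (23 426 points, vectorized; ties broken to the lexicographically
smallest tuple), objective = R² of the univariate linear fit of total
pathlength on the composite — pathlength being the field's benchmark economy
measure. e^(−log ST) is read with the natural log, i.e. 1/ST ≥ 1, penalizing
tortuous paths.

The anchored component transform is the line through (median of with-errors
group → 0.6, median of error-free group → 0.9), clamped to [0, 1]; clamping
never activates between the anchor medians. The with-errors group is every
exercise with ≥ 1 handling error of any kind. PCA weights use the correlation
(standardized) matrix by default — for two standardized variables the leading
eigenvector is (1, 1)/√2, giving exactly (0.5, 0.5), which is the right
behaviour when both components are already on the same [0, 1] scale; a
covariance-based variant is available. Proficiency applies only the lower
Z bound (mean − 2·SD of error-free PS, sample SD): an upper bound would
absurdly disqualify the smoothest performers.

## Cutoff detection

"Sudden change" is operationalized as a two-segment piecewise-linear least
squares fit: breakpoints are scanned on a 0.01-resolution SBR grid, each side
fitted independently (discontinuity allowed — a threshold phenomenon is a
jump, not a spline knot), each side requiring ≥ 2 points, minimizing total
SSE. Count outcomes (handling errors) are first averaged within 0.1-wide SBR
bins. When the two-segment fit improves R² over a single line by < 0.01 the
result is flagged `no_clear_cutoff` rather than suppressed. The estimator
recovers the generator's θ = 1.5 within ±0.06 across 20 replicate cohorts of
200 exercises (the packaged tests assert ±0.15). Group comparisons use the
Welch (unequal-variance) t-test.

## Problem sizes and determinism

Packaged tests run cohorts of 40–200 exercises and 20 replicate seeds for the
threshold-recovery check — sizes at which every Monte-Carlo assertion has
comfortable margin while the whole suite stays fast. All randomness flows
from one master seed through named substreams (CRC-derived SeedSequence
spawns, kept below 2³¹), so cohort manifests and score tables are
byte-identical across reruns with the same seed.

## Known limitations

Dx magnitudes depend on sample rate and smoothing window and are only
comparable within one acquisition configuration. The anchored transform
requires both error groups non-empty with distinct medians and fails loudly
otherwise. The breakpoint grid assumes the true cutoff lies strictly inside
the observed SBR range. Real endoscopic video ingestion (stereo calibration,
temporal filters, occlusion handling) is out of scope; the imaging module's
marker segmentation is intentionally minimal.
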