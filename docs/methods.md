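# Methods

## Scope and data model

`ergokin` measures segment *posture* (arm inclination, trunk sagittal
inclination) and *movement* (inclination velocity, generalized velocity)
from a body-worn six-axis IMU, and quantifies how the choice of sensor
path and velocity definition changes half-workday exposure summaries.
All angles are in degrees and velocities in °/s; recordings are plain
CSV (time, triaxial accelerometer in g, triaxial gyroscope in °/s) at a
nominal 25 Hz with a YAML sidecar for metadata.

## Synthetic recordings

Field recordings of this kind are rarely shareable, so the package
includes a rigid-body simulator whose outputs drive every test.

**Kinematics.** A segment rotates about a fixed joint. The scripted
inclination θ(t) is a raised cosine per bout, `θ = A/2·(1 − cos 2πt/T)`,
which starts and ends each bout at 0° with zero velocity (C¹ continuity
for free); axial rotation ψ(t) is a constant-rate spin about the segment
long axis. The gravity direction in the segment frame is then
`(cos ψ sin θ, −sin ψ sin θ, cos θ)`, the inclination velocity `|θ̇|`
and the generalized velocity `sqrt(θ̇² + ψ̇² sin²θ)` — closed forms that
make the spherical-triangle dominance (generalized ≥ inclination) exact
in the ground truth.

**Sensor model.** The sensor sits on the segment axis `lever_arm` metres
from the joint (default 0.25 m, an upper-arm mid-deltoid placement; the
value is a declared default and is swept in tests). Its specific force
includes the centripetal (ω²r) and tangential (αr) terms of the scripted
rotation — the artifact that corrupts accelerometer-only inclinometry at
speed. Gyroscope output adds a constant per-axis bias (default
0.01 rad/s), optional bias random walk, and white noise (0.005 rad/s);
accelerometer white noise defaults to 0.1 m/s². These magnitudes mirror
the Kalman design values so the filter is evaluated under matched
conditions. Scripts whose true rates exceed the ±1000 °/s hardware range
are rejected. One seeded generator per recording makes every output
bit-reproducible.

**Postural jitter.** Scripted bouts alone are spectrally far too clean:
real manual-handling movement carries power up to roughly 5 Hz (the
rationale for the 25 Hz sampling / 5 Hz filtering conventions of this
field), and that broadband content — not the smooth reaches — is what
drives the large accelerometer-path velocity inflation observed in field
comparisons. The generator therefore superimposes a band-limited
inclination jitter (sum of six random sinusoids, default 0.5° RMS in
1.5–4 Hz) with exact ground truth. The amplitude was chosen so that a
simulated cohort reproduces the approximate 2× accelerometer-vs-fused
median-velocity ratio reported from field work; it is not fit to any
test statistic. Simple-movement benchmarks set the jitter to zero.

**Cohort scripts.** `cohort_scripts` emulates order-picking/palletizing
work: swing bouts of 40–100° amplitude and 1.8–3.5 s period separated by
3–10 s rests; 60 % of arm bouts add a 30–90 °/s axial rotation; trunk
bouts use 15–60° flexion and no axial term. A run of six simulated
subjects yields group-mean median velocities of roughly 26 (fused
inclination) to 79 °/s (accelerometer generalized), bracketing the
16–71 °/s reported from warehouse work, with the same ordering.

**What the generator does not emulate.** Soft-tissue artifact, sensor
translation of the whole body (walking), impact transients from box
handling, magnetometer channels, and realistic field amplitude spectra
beyond the bout library. Passing tests therefore demonstrate correctness
of the processing chain and the direction and rough size of the
sensor/velocity-definition effects — not quantitative agreement with any
particular field population.

## Calibration

The reference posture gives the segment's vertical in sensor
coordinates (median of a 3-s window for the arm, mean for the trunk);
the direction posture (90° abduction / forward bow) gives the
forward axis. "Stable" windows are operationalized as the 3-s sub-window
of the labelled interval minimizing total accelerometer variance. The
rotation is built by Gram–Schmidt: vertical = reference vector, forward
= direction vector minus its vertical component. An Euler-angle
factorization (`Rz·Ry·Rx`) of the same rotation is available for
reporting; building `R` directly avoids solving for angles. Vectors
closer than 5° are rejected as a calibration failure, and windows whose
resultant falls below 0.5 g are treated as invalid captures. The body
convention is right-handed, z up, x forward toward the direction
posture.

## Orientation estimation

**Accelerometer path.** 25-tap Blackman-window FIR, 5 Hz cutoff
(−6 dB convention) at 25 Hz, applied with reflect padding so the
linear-phase group delay (12 samples) is exactly compensated; the
filtered vector is rotated to the body frame and normalized per sample.
Tap count and cutoff are configurable.

**Fused path.** Signals are polyphase-resampled 25→128 Hz (Kaiser-8
window; a 1 Hz tone survives the 25→128→25 round trip to within 0.01 %;
linear interpolation is available behind a switch). A linear Kalman
filter runs at 128 Hz with state `(ĝ, b)`: predict rotates ĝ by
`−(ω − b)·dt` using the exact Rodrigues rotation with trapezoidal
averaging of consecutive gyro samples (a rectangle-rule first-order step
leaves a half-sample phase lag of ~0.3° at 70 °/s — measurable against
ground truth), while the covariance uses the standard linearization with
process noise `(0.005·dt)²` (gravity rows) and `(0.0005·dt)²` (bias
rows) and measurement noise `(0.1/9.81)²` on the normalized
accelerometer direction. ĝ is renormalized every step. The gravity
*vector* series (not the scalar angle) is resampled back to 25 Hz and
renormalized, so angles and velocities derive from one consistent
series. Initial state: gravity from the first accelerometer sample, zero
bias, loose diagonal covariance. The bias component parallel to gravity
is unobservable from gravity measurements alone and simply keeps its
prior; the orthogonal components converge within a few per cent in under
a minute of quiet wear. The first 2 s of output are treated as filter
warm-up and excluded from exposure metrics (error benchmarks exclude
5 s to let the bias transient settle).

## Kinematics and exposure

Angles use the chord formula `2 arcsin(|Δg|/2)`; the trunk sagittal
angle is `atan2(g_x, g_z)` (forward positive, continuous through deep
bows), with samples within 1° of the lateral axis flagged invalid.
Velocities use a first-order backward difference (matching the pairwise
generalized-angle construction; a central scheme is available for
sensitivity analysis) and are absolute-valued. No smoothing is applied
after the orientation stage.

Summaries report the mean, percentiles at ranks {1, 5, 10, 25, 50, 75,
90, 99} (linearly interpolated empirical quantiles — the convention most
affects the 1st/99th ranks and is configurable), the 10th–90th
percentile range, and proportions of time per criterion: arm angle <20°,
>30°, >45°, >60°, >90°; trunk angle −10°–20°, <20°, >30°, >45°, >60°,
>90°; velocity <5 °/s and >90 °/s; and combined rest indicators
(angle <15°/<20° together with velocity <5 °/s, plus the −10°–20° band
for the trunk). Inequalities are strict, matching the criterion labels;
criteria met by no sample report 0 with a flag.

Threshold conversion equates within-subject percentile ranks: the
fractional rank of the threshold in the source velocity distribution
(linear interpolation on the sorted sample) indexes the target
distribution. The mapping is monotone in the threshold, equivariant
under consistent monotone transformations, and exact under
`target ≡ source`; out-of-range thresholds clamp to the empirical
extremes with a warning.

## Group statistics

Within-subject differences pass a normality gate — Shapiro–Wilk at
α = 0.05 (configurable) OR the moment fallback |skewness| < 2 and
Pearson (non-excess) kurtosis < 6, the OR reflecting the t-test's
robustness to mild non-normality — then a paired t-test or Wilcoxon
signed-rank (exact for n < 15, tie-corrected normal approximation
otherwise), two-sided, significant at α = 0.01 in lieu of an explicit
multiplicity correction. Agreement analysis: Pearson r, ordinary
least-squares fit for angles, zero-intercept slope `Σab/Σa²` for
velocities (which vanish together), and Bland–Altman mean difference
with ±1.96 SD limits. Conversion factors between velocity conventions
chain multiplicatively; the pipeline reports both the chained and the
directly fitted one-step factor (2.90 vs 2.91 on the default six-subject
cohort — same near-agreement structure as the published 4.47 vs 4.46,
with the absolute size depending on the cohort's movement content).

## Numerical and degenerate-input choices

Unit-norm tolerances: 1e-9 for ground truth and calibration, 1e-6 for
estimated gravity series. Constant paired differences short-circuit to
p = 1 with a flag; constant samples pass the normality gate flagged
(Shapiro–Wilk undefined); zero-variance inputs to the agreement fit flag
r as undefined. NaN gaps up to 1 s in recordings are linearly bridged
and logged, longer gaps reject the file, as do non-monotone timestamps
and malformed headers. All randomness flows from explicit integer seeds
and `numpy` Generators; reruns are byte-identical.

## Problem sizes

Defaults are sized for interactive use: 120 s benchmarks and 150 s
six-subject cohorts at 25 Hz, which resolve the velocity percentiles and
effect orderings with comfortable margins. All durations, cohort sizes
and rates are parameters, and the pipeline scales linearly in recording
length.

## Known limitations

- The fused path estimates gravity direction only (no heading); axial
  arm rotation enters the generalized velocity only through its
  geometric effect on the gravity vector, as intended by that measure.
- Trunk generalized velocity and cumulative generalized angles are out
  of scope, as is lateral trunk inclination.
- The jitter component is a stand-in for unmodelled broadband movement;
  conversion factors computed on synthetic cohorts depend on its level
  and should not be read as field-calibrated constants.
- The simulator's misalignment model rotates the sensor rigidly; no
  soft-tissue motion between sensor and bone is modelled.
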