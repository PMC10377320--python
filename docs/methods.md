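# Methods

## Arm model

The right arm is a serial chain of upper arm (L1), forearm (L2) and
hand (L3) with six revolute joints (q1 shoulder abduction/adduction, q2
flexion/extension, q3 internal rotation, q4 elbow flexion, q5
pronation/supination, q6 wrist flexion).  The chain uses **standard
(distal) DH convention**, each row contributing
Rz(θ)·Tz(d)·Tx(a)·Rx(α); rows carry (α = ±π/2 alternating, d = −L1 on
row 3, d = −L2 on row 5, a = L3 on row 6) and no θ offsets.  Default
segment lengths are L1 = 0.30 m, L2 = 0.25 m, L3 = 0.18 m — plausible
adult values, everywhere overridable, and in cohort analyses replaced
by per-participant medians of the skeleton's inter-joint distances.

Two geometric facts of this table shape everything downstream:

* **Full elbow extension (q4 = 0) is singular.**  So are q2 = 0
  (hanging arm, where the q1/q3 axes align) and q6 = 0.  The
  extended-arm configuration q2 = q4 = q6 = 0 has σ_min/σ_max ≈ 1e−17
  and serves as the singular fixture in tests.
* **The neutral (straight) hand is q6 = π/2**, not 0: at q6 = 0 the
  hand segment is perpendicular to the forearm.  Exercise scripts and
  the wrist-angle extraction treat q6 = π/2 as neutral.

The joint-2 θ entry is driven by q2; a published form of this table
repeats q3 there, which is inconsistent with six independent DOF and is
treated as a typo.

Units are metres and radians throughout.  The Jacobian therefore mixes
m/rad and rad/rad rows; KMI is reported in raw model units with no
characteristic-length normalisation, so absolute values compare only
within one segment-length choice.  Row order is fixed linear-then-
angular, which the determinant-based indices depend on.

## Manipulability indices

With singular values σ₁ ≥ … ≥ σ₆ of J: KMI = Πσᵢ, Id = σ₁/σ₆,
LCI = σ₆/σ₁.  KMI is evaluated as |det J| — identical to
sqrt(det(J Jᵀ)) for the square Jacobian but numerically far better
conditioned (forming J Jᵀ squares the condition number).  A config
switch (`kmi_definition: det`) exposes the squared variant
det(J Jᵀ) = (det J)² for comparability with analyses that skip the
square root.  The singularity threshold is σ_min < 1e−12·σ_max, the
standard numerical rank tolerance: below it Id is +inf and LCI and KMI
report 0/flagged.  Index series are resampled to the EMG timeline by
linear interpolation on a uniform grid (endpoints preserved; no
overshoot).

## Pose extraction

Skeleton frames give 3D joint positions only, so the six angles are
reconstructed geometrically:

* a trunk frame (z down the spine, x medial from the right shoulder,
  y = z × x) makes shoulder angles camera-invariant; in it the elbow
  sits at −L1(cos q1 sin q2, sin q1 sin q2, −cos q2), inverted by
  atan2.  With this table q2 is the elevation and q1 the elevation
  plane — q1 = 0 elevates in the frontal plane (abduction).  A pure-q1
  "abduction" is not possible here: at q2 = 0 the q1 axis runs along
  the hanging arm.
* q4 = π − angle(elbow→shoulder, elbow→wrist) (0 at full extension,
  always ≥ 0 — the anatomical elbow does not hyperextend);
* q6 = atan2(h·f, h·(f×n)) with forearm axis f, hand direction h and
  elbow-flexion-plane normal n.  When the elbow passes through full
  extension the plane degenerates; the previous frame's normal is
  reused (and scripts keep a small residual flexion, see below).
* q3 and q5 are unobservable from joint positions (they rotate about
  segment axes) and are set to 0 with a low-confidence flag rather
  than guessed.

Validation is by construction: rendering a known trajectory through the
forward kinematics and extracting it back recovers q1, q2, q4, q6 to
~1e−15 rad noise-free, and q4 to < 1.5° RMSE under 5 mm isotropic joint
noise with the default 5-frame moving-median smoothing.  Smoothing is
disabled (window 1) in exactness tests, since a median filter biases
angles at curvature extrema by ~q̈·Δt²/2.

Degraded frames (non-finite points, or shoulder–elbow / elbow–wrist
distance < 1 cm) carry the last valid pose forward and are flagged;
leading degraded frames back-fill from the first valid pose.

## EMG pipeline

Fixed order: band-pass → rectify → envelope → MVC-normalise.

* **Filter**: Butterworth band-pass 20–300 Hz of overall order 8 (4
  pole pairs per edge), applied forward-backward.  Zero-phase
  application keeps activation onsets aligned with trial markers at
  the cost of squaring the magnitude response; the passband stays
  within 5 % at 100 Hz and a 5 Hz component attenuates ~700-fold.
* **Envelope**: running median over 3500 samples (2.33 s at 1500 Hz),
  coerced to 3501 because a centred window must be odd (logged).
  Edges shrink the window and take the nearest-rank median of the
  available samples, avoiding padding artefacts at trial boundaries.
  Interior windows are computed by a rolling median (pandas); the edge
  definition is exact by direct selection.  Note the window is longer
  than a 2 s phase, so envelopes of brief plateaus are smoothed below
  their design level; plateau-recovery checks use ≥ 8 s plateaus.
* **MVC**: the maximum of the rectified, band-passed ~3 s maximal-
  contraction recording, per muscle — filtered rather than raw so the
  normaliser lives on the same scale as the trial signals.  A zero MVC
  is returned but refused for normalisation.

Trials arrive as marker files (trigger start/end bracketing the trial,
activity start/end the movement); automatic onset detection is out of
scope.  Phase windows split the activity window at configured fractions
of its duration.  Trials are aligned by linear resampling to the
rounded mean trial length.

## Effort metrics and statistics

RMS, MAV, WL and SSC are computed per phase and per whole activity
window **on the signed band-passed μV signal** (not the normalised
envelope) so the 100 μV SSC threshold and the μV-scale means retain
physical meaning; RMS and MAV are identical either way, WL/SSC operate
on raw sample differences.  The SSC comparison is ≥ threshold (ties
count).  Aggregation is two-level: mean over a participant's trials,
then mean ± sample sd (n−1) across participants, n recorded at each
level — the participant is the sampling unit.

Muscle comparisons use the two-sided Wilcoxon rank-sum test on one
value per participant.  For combined n ≤ 12 the null is enumerated over
all rank assignments using midranks (valid under ties; C(12,6) = 924
cases at worst); larger samples use the tie-corrected normal
approximation with continuity correction.  Under a null simulation at
n = 19 the empirical type-I error is ≈ 0.047 at α = 0.05.  The
Bonferroni family is the 6 muscle pairs within one (metric, phase)
cell — per-cell rather than global, switchable — giving the 0.05/6 ≈
0.008 reporting threshold.

## Synthetic cohort

The generator emulates the *structure* the analysis assumes, not the
physiology: per trial, minimum-jerk joint trajectories between scripted
phase targets rendered to 30 Hz skeleton frames through the forward
kinematics (plus a per-participant rigid camera transform and isotropic
Gaussian joint noise, default 5 mm), and 1500 Hz sEMG built as a
20–300 Hz band-limited Gaussian carrier, amplitude-modulated by
trapezoidal phase-locked activation (0.3 s ramps) on top of 5 μV RMS
white baseline noise.  It does **not** model motor-unit statistics,
crosstalk, electrode drift, skeleton occlusion or any intrinsic
EMG–kinematics coupling — so passing tests demonstrate the pipeline's
correctness and the scripts' designed structure, not physiological
findings.

Calibration choices, measured once and frozen:

* the carrier is normalised to unit **median absolute** amplitude, so
  the median-envelope pipeline reads the designed level × MVC directly
  (envelope of a designed 250 μV plateau ≈ 241 μV, ~−4 % bias from
  double filtering and baseline noise); consequence: phase RMS ≈
  1.49 × level × MVC for a Gaussian carrier;
* MVC recordings scale their plateau by 1/5.5, the measured
  peak-to-median ratio of the band-limited carrier over ~2.5 s, so the
  peak-based MVC measurement lands near the designed value (±~25 %,
  realistic for a peak statistic).

Defaults mirror the study design: 19 participants, 10 trials per
exercise, 2 s rests and 2 s phases (stretched per trial by ~8 %
duration jitter), per-trial ±5 % activation jitter, per-participant
segment lengths N(0.30, 0.02)/N(0.25, 0.015)/N(0.18, 0.01) m and
lognormal MVC scaling (σ = 0.15) around fcu 420 / ecu 480 / bb 520 /
dm 380 μV.  Exercise 1 (frontal plane): abduction to 90°, elbow
flexion to 2.2 rad, extension to 0.15 rad, wrist flexion/extension
(±0.9 rad about neutral) with the arm extended, return; exercise 2
(transverse plane): abduction, elbow flexion to 1.7 rad held through
the wrist phases, extension + return.  "Extension" targets stop at
0.12–0.15 rad rather than 0: people rarely reach the exact singular
pose, and it keeps the flexion-plane normal defined for wrist-angle
recovery.  The activation map makes DM loudest in abduction/elbow
phases, BB in elbow flexion, FCU in wrist flexion and ECU in wrist
extension; every phase's designed top muscle is recovered as the RMS
argmax in ≈ 98 % of trial-phases at default noise.  A null (all-equal
activation) scenario is generable for type-I-error studies by clearing
the activation maps.

All randomness flows through one seed: streams are keyed by
(seed, participant, exercise, trial, channel), so regenerating any
sub-tree is reproducible and two runs with the same seed are
byte-identical, including written CSV trees and analysis TSVs.

## Problem sizes and numerical choices

The acceptance script and end-to-end tests run the cohort at the full
study size (19 × 2 × 10) in memory; file-tree round trips are exercised
at 1–2 participants.  Oracle suites use 200 random poses (Jacobian vs
central differences, step 1e−6, agreement < 1e−5), 500 random matrices
(index vs SVD, < 1e−9 relative), 50 random windows (features vs brute
force, exact for SSC), and 2000 null replicates for the type-I error.
Ties at the exact-enumeration boundary use a 1e−9 slack on the
deviation comparison; linear interpolation is used for all resampling
(cannot overshoot, endpoints exact).

## Limitations

Absolute KMI values depend on the mixed-unit Jacobian and segment
lengths; only within-model comparisons are meaningful.  q3/q5 are
assumed 0, so exercises relying on forearm rotation would need an
instrumented forearm axis.  The envelope window (2.33 s) exceeds the
default phase duration, smearing phase-locked envelopes.  Plots are
qualitative companions, not analysis surfaces.  The left arm is not
mirrored; force/dynamic manipulability and frequency-domain EMG
features are out of scope.
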