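# Methods

This note records the models the package implements, the conventions
and defaults it commits to, and what its synthetic-data experiments do
and do not demonstrate.

## Continuous relative phase

A normalized cycle (101 points, 0–100%) is mean-centered and its
analytic signal built with the FFT-based discrete Hilbert transform.
The instantaneous phase is the four-quadrant arctangent
`φ(tᵢ) = atan2(H(x)(tᵢ), x(tᵢ))`: a two-quadrant `arctan(H/x)` cannot
represent a full phase cycle, so the four-quadrant form is the only
workable reading of the Hilbert-phase method. Signals are centered but
not amplitude-normalized — phase is already amplitude-invariant, and
centering is the minimal requirement for a meaningful analytic signal.

Conventions, fixed after verifying them against the discrete
transform: the phase of `cos(2πt/T)` advances +90° over a quarter
period; a signal lagging by a fraction Δ of the period, passed as
signal 2, yields CRP ≈ +360·Δ degrees. CRP values are wrapped to
(−180°, 180°]; RMSE between CRP curves uses the wrapped
(smallest-angle) difference. The discrete transform has edge effects
on a 101-point grid; analytic identities are asserted away from the
first/last five grid points.

Pairings. Intralimb CRP is hip-vs-knee within one side (hip = signal
1), each side segmented at its own heel strikes. Interlimb CRP pairs
corresponding joints across limbs (sound/right side = signal 1) and
must be computed on a common time base: both limbs are segmented at
the *reference* (right/sound) side's heel strikes. Per-joint interlimb
curves are retained; their pointwise circular mean is the summary
interlimb series. Patient "CRP deviation" is the wrapped RMSE against
the healthy-group mean CRP curve (pointwise circular mean over a
reference cohort) for the same pairing and window; the comparator is
configuration-exposed because between-sides comparison is equally
defensible.

## Decomposition index

A joint is paused where |angular velocity| < 5 °/s (strictly; exactly
5 counts as moving). Decomposition requires exactly one paused joint
(exclusive-or): both-paused points do not count, taking "one moves
while the other pauses" literally. Whole-cycle DI divides by all grid
points; stance and swing DIs divide by the respective phase length so
each can independently approach 1 (dividing by the whole cycle would
bound their sum by the whole-cycle DI, which contradicts how the
phase-specific indices behave).

Velocity is obtained by central finite differences on the 101-point
grid, converted to °/s with the stride duration. By default curves
are first harmonically smoothed at order 12: with ~0.5° measurement
noise, raw finite differences at 100 Hz produce ~20 °/s velocity
noise that swamps the 5 °/s criterion. Order 12 retains imposed pause
plateaus reasonably while suppressing chatter; the raw-curve option
is kept (and is the right choice for noiseless data, where it is
unbiased — the zero-noise round-trip of an imposed 30%-of-cycle pause
recovers DI 0.29–0.30).

## Preprocessing

Cycles are heel-strike to heel-strike. With no events attached, heel
strikes are detected as hip-angle local maxima (maximum hip flexion
closely precedes heel strike in level walking) separated by at least
half the dominant period, the dominant period coming from the first
prominent autocorrelation peak. Each cycle is linearly resampled onto
101 points (both endpoints on-grid); the stance/swing boundary is the
toe-off position as a percentage of the cycle.

Smoothing is harmonic regression: ordinary least squares on the basis
{1, sin(2πkt/100), cos(2πkt/100)}, k = 1..K (default K = 6), i.e. a
linear projection — deterministic, convex, idempotent, with residual
RMS non-increasing in K. No other filtering is applied; truncation of
the harmonic series is what removes riding waves. The "representative"
cycle of a trial is the one with minimal RMSE to the within-trial mean
curve (configurable).

A band-limited curve evaluated directly on the 101-point grid refits
its own harmonic order to numerical precision; a curve that passed
through time-domain sampling plus linear resampling carries ~0.01°
interpolation residue (well inside the 0.1° normalization tolerance).

## Synthetic gait generator

The generator is the package's stand-in for wearable motion-capture
recordings. Joint angles are band-limited sums of sinusoids at
stride-frequency multiples (default 4 harmonics): the hip is an
all-cosine series, placing maximum flexion exactly at heel strike (the
same convention the event detector uses); the knee is the harmonic
projection of two periodic bumps — a stance-flexion bump at ~35% of
stance and a dominant swing-flexion peak placed mid-swing. Curves are
affinely rescaled after pause application so the per-cycle
peak-to-peak amplitude equals the profile RoM exactly. The
contralateral limb is the same construction shifted half a cycle
(rounded to one sample). Pause windows are zero-order holds over the
stated window with 5-sample cosine ease-in/out ramps *outside* the
window (so the held duration matches the ground truth; ramps centered
inside would shorten it measurably).

Thigh inertial channels derive from the thigh segment angle θ (hip
flexion from vertical): gyro = dθ/dt; accelerometer = gravity
component plus centripetal (axial) and tangential (perpendicular)
terms at a 0.25 m sensor offset below the hip; the mediolateral axis
carries noise only. Gaussian noise (default sd 0.5°, gyro 0.5 °/s,
accelerometer 0.01 m/s²) is added last.

Group defaults use published group means: healthy speed 0.92 m/s,
RoM_hip 62.33°, RoM_knee 44.38°, swing fraction 0.53; stroke speed
0.18 m/s with reduced, asymmetric RoMs (affected knee 35.92°, hip
41.42°) and swing fractions 0.70/0.57; amputee RoMs 59.52/55.65°
(hip) and 43.09/42.80° (knee) with swing 0.57/0.54. Stride durations
are back-computed from speed with representative stride lengths
(healthy 1.10 m, stroke 0.60 m, amputee 1.00 m — cadence is not
reported for these groups); amputee speed (also unreported) defaults
to 0.70 m/s, a typical transfemoral self-selected value. Patient
profiles carry default knee pause windows (larger on the affected
side) so the groups reproduce the qualitative DI ordering: stroke >
amputee > healthy and affected ≥ sound. Inter-subject variability
multiplies each continuous parameter by lognormal(0, 0.05) jitter
under a per-subject seed; swing fractions are clipped to (0.2, 0.8).

What the generator does *not* emulate: ground-reaction forces, ankle
motion, double-support timing asymmetries, stride-to-stride temporal
variability (every cycle of a trial has identical timing), sensor
drift, or soft-tissue artifact. Passing tests therefore demonstrate
correctness of the analysis chain and qualitative group behavior, not
clinical validity on recorded patients.

## Synergy models

**Datasets.** Interlimb tasks use 4 input channels (contralateral hip
and knee angles plus their finite-difference velocities) and target
the estimated side's hip or knee angle; the intralimb task uses the
ipsilateral thigh IMU (gyro + 3-axis accelerometer) and targets the
knee angle — one separate single-output model per target. Inputs are
z-normalized per channel with statistics from training subjects only
(a guard flag prevents silent re-normalization); targets stay in
degrees. Sequences are raw time series at the trial sampling rate.

**PCA-CLME.** Eigendecomposition of the covariance of stacked
[inputs; target] pooled over training subjects; the component count k
is the smallest reaching the retained-variance target (default 0.95,
exposed; 1.0 keeps every non-degenerate component and makes recovery
of an exactly linear coupling exact). Prediction solves the
least-squares score problem through the input loading block and maps
scores through the target block — an affine map. Rank-deficient input
blocks reduce k with a warning.

**LSTM.** Forget-gate recurrence (sigmoid f/i/o gates, tanh candidate
— the candidate activation is not spelled out in the source
formulation and is taken as the standard tanh), hidden size default
50, one linear output unit, zero initial states. Training: mean
squared error by truncated backpropagation through time over
fixed-length windows (default 200 samples), Adam at 1e-3, 50 epochs
default, global gradient-norm clipping at 5, targets standardized
internally with training statistics. Weights initialize uniform
(±1/√H) with forget biases at 1. Everything is numpy; a fixed seed
gives bit-identical weights. Analytic BPTT gradients are verified
against finite differences in the tests.

**Evaluation.** Leave-one-subject-out: one session per subject, the
model fitted on the rest, normalization statistics recomputed per
session from that session's training subjects. Metrics per session —
RMSE, MAE, Pearson correlation, R² — plus across-session means. A
master seed fans out per-session seeds through `SeedSequence`.

Desk-scale configuration: the bundled experiments and the
reproduction script use 8 subjects × 6 cycles, hidden size 16,
20–30 epochs, learning rate 0.01, 120-sample windows — sizes chosen so
the full suite runs in minutes on one CPU while preserving the
qualitative result (LSTM beats the linear PCA reconstruction by a wide
margin whenever the coupling is nonlinear; on an exactly linear
coupling both succeed, PCA exactly and the LSTM to a few percent of
target range). The deliberately nonlinear test coupling passes the
contralateral target joint's angle through a tanh saturation (scale
12°) with a ±60% phase-dependent gain.

## Determinant analysis

Collinearity first: VIF per predictor (regressing it on the others;
infinite VIF excludes a predictor from selection) and condition
indices of the unit-length-scaled design including the intercept.
Predictors with VIF > 10 are reported, not dropped (auto-drop is a
flag). Selection is classical bidirectional stepwise OLS: enter the
candidate with the smallest partial-F p-value if ≤ 0.1, then remove
any retained predictor with p > 0.1; ties break on column order;
termination when a full pass changes nothing.

A statistical note: with five pure-noise candidates each screened at
α = 0.1, at least one false entry occurs in ~41% of replicates — this
is a property of stepwise selection at that α, not an implementation
artifact. The tests therefore assert (a) the true predictor is always
recovered in a strong-signal construction, (b) the exact-selection
rate matches the analytic ~0.9⁵ expectation, (c) selection is
invariant to predictor rescaling, and (d) on pure noise the empty
model is returned in well over 40% of replicates.

## Numerical choices and degenerate inputs

- Constant (zero-variance) signals: phase extraction raises a
  degenerate-signal error; PCC of a zero-variance window is NaN with
  RMSE still reported.
- Harmonic fitting beyond order 49 on 101 points is rejected
  (rank-deficient design).
- Pause threshold exactly at 5 °/s counts as moving (strict
  inequality for "paused").
- The angle wrap is (−180°, 180°], with ±180° mapping to +180°.
- LSTM training aborts on non-finite loss with learning-rate guidance
  rather than returning garbage weights.

## Known limitations

- The generator's cycles are exactly periodic within a trial; cycle
  segmentation and normalization are therefore easier than on real
  data with temporal jitter.
- Interlimb CRP of multi-harmonic waveforms under a half-cycle shift
  is not a constant 180°; only single-harmonic signals give the
  textbook antiphase constant. Group-level interlimb summaries should
  be read as deviations from a reference curve, not as absolute phase
  offsets.
- The stance/swing DI normalization (per phase duration) is an
  interpretation; the whole-cycle-denominator variant is computable
  from the same masks if needed.
- LOSO with 8 synthetic subjects measures generalization across the
  generator's lognormal parameter jitter, which is narrower than real
  inter-subject anatomical and stylistic variation.
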