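# Methods

This note records the models implemented by tremorkit, the parameters that
matter, the numerical choices behind them, and what the synthetic data can
and cannot establish.

## Test-pattern geometry

The 19 tests are represented as parametrized reference curves in a
device-frame coordinate system with Y up, the X–Y plane coronal, Y–Z
sagittal and X–Z transverse; all positions are metres.  Patterns 1–2 are
fixed targets, 3–11 are screen curves embedded at constant Z, 12–14 are
physical 3D lines with fixed printed lengths (0.40 m coronal, 0.20 m
sagittal, 0.48 m spanning all axes), and 15–19 reuse the geometry of a
base pattern (2, 3, 3, 8, 13 respectively) under a force field.

The screen-to-workspace mapping of the original apparatus is not
recoverable from recordings, so 2D extents derive from a configurable
`workspace_scale` (default 0.30 m, a comfortable seated reach).  Open
geometric choices were fixed as follows: the spirals are Archimedean
(r = k·θ) with 3 turns for pattern 8 and 5 for the "narrower" pattern 9 at
equal outer radius; pattern 11 is a sinusoid whose envelope decays
linearly between two converging borders; pattern 14 is a three-segment
polyline of 0.16 m per axis.  Deviation from a reference curve is the
Euclidean distance to its nearest point: closed form for points and
(poly)lines, and a 2048-point parameter scan refined by bounded scalar
minimization otherwise (accurate to ≲1e-9 m for these geometries, checked
against 1e5-sample brute force).  Arc lengths use exact formulas for
segments and ellipses (complete elliptic integral) and adaptive quadrature
of the analytic speed elsewhere.

The analysis channel of a test is the per-sample deviation series; the
target tests (2/15) use the planar X–Y distance from the target, and the
rest test (1) uses the highest-variance linearly detrended position axis,
since rectifying a zero-mean tremor into a distance would double its
apparent frequency.

## Virtual force fields

Three loads perturb the hand during dynamic tests, with the device's
printed constants as defaults: a constant force clamped to 5 N magnitude
(the cap applies to the magnitude, not per axis), a spring F = K·X
restoring toward the reference (K swept linearly over [0, 0.0005] N/m —
the sweep shape is a modelling choice), and a mass–spring–damper
F(t) = M·ẍ + B·ẋ + K·x with M = 0.05 kg and B = 0.0015 kg/s, implemented
as the standard second-order form.  Forces returned by the library are the
loads felt by the hand; spring and damper terms oppose deviation and
velocity (the sign convention is ours — only magnitudes are physically
constrained).

## Synthetic recordings

The simulator replaces the haptic device and the patient cohort.  A
recording is

    x(t) = voluntary(t) + tremor(t) + measurement noise,

sampled at 100 Hz (the device's rate).  Voluntary motion is a minimum-jerk
traversal (s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ along arc length) of the pattern from
start to end, the standard model of point-to-point reaching; static tests
hold the target.  Measurement noise is white with σ = 5·10⁻⁵ m, well above
the encoder scale but small against tremor.

Tremor has class-specific statistical structure:

- **physiological (healthy)**: a stationary AR(2) process with resonance
  at the tremor frequency — a linear stochastic signal.  The pole radius
  is set as exp(−π·bw/fs) with bandwidth bw = 0.8 Hz so the spectral shape
  is independent of the generation rate.
- **PD**: a harmonic carrier whose amplitude and phase are modulated by
  smoothed logistic-map streams (r = 3.9, iterated at 10 Hz, low-passed at
  3 Hz; positive Lyapunov exponent) plus a second harmonic locked at twice
  the carrier phase.  The phase-locked harmonic produces the quadratic
  phase coupling — hence nonzero bispectrum — expected of a nonlinear
  chaotic signal.
- **ET**: the carrier with linear-stochastic (AR(1), ~0.1 Hz bandwidth)
  amplitude modulation and no phase-coupled harmonic — intermediate
  between the other two.

Class centre parameters are modelling choices in the range movement-
disorder studies report, not measured constants: PD 5 Hz / 3 mm RMS,
ET 7 Hz / 1.5 mm, healthy 10 Hz / 0.3 mm.  Per-subject parameters jitter
around the centres (frequency uniform ±0.4 Hz, amplitude log-normal
σ = 0.2).  A `separation` knob (default 1) shrinks class frequencies
(linearly) and amplitudes (log-linearly) toward the pooled mean and mixes
each class's canonical process with the other two (power weights shrink
toward uniform), producing progressively overlapping cohorts; the overlap
series used in the checks is separation ∈ {1.0, 0.3, 0.1}.

When a pattern carries a force field the trajectory is instead the
response of a hand model — a 1 kg point mass whose voluntary intent is
tracked by a critically damped controller with 3 Hz natural frequency
(stiffness 355 N/m), chosen so that tremor frequencies lie above the
closed-loop resonance.  Tremor enters as the disturbance force that would
reproduce the displacement model exactly on the force-free hand, so added
viscous/inertial loads strictly attenuate the tremor band; this realizes,
qualitatively, the clinical observation that viscous friction suppresses
tremor.  Integration is fixed-step semi-implicit Euler at 1 kHz (symplectic
for the undamped case; energy drift < 0.01 % over 20 s), decimated to
100 Hz.  The tremor and noise random streams are spawned from the subject
seed in fixed order, so paired force/no-force runs share their
disturbances bit-exactly.

The default cohort is 210 healthy + 34 ET + 120 PD training cases (364)
with 156 validation cases drawn with the same class proportions
(largest-remainder rounding: 90/15/51); recordings default to 20 s of the
rest test.  Everything is reproducible bit-exactly from a master seed.

What the generator does *not* emulate: medication state, fatigue and
time-of-day effects, re-entrainment between voluntary motion and tremor,
non-stationary freezing/bradykinesia episodes, inter-session variability
and misdiagnosed training labels.  Passing tests therefore show that the
pipeline recovers class structure *of the kind modelled*, not that the
feature set separates real patients.

## Spectral features

All estimators share one settings object: Hann window, 256-sample
segments, 50 % overlap, per-segment linear detrend (the PSD needs ≥ 256
samples, the higher-order estimates ≥ 512).  The PSD is the one-sided
Welch density.  Higher-order spectra are direct FFT-based estimates
averaged over segments, unnormalized: B(f₁, f₂) = E[X(f₁)X(f₂)X*(f₁+f₂)]
on the principal region 0 ≤ f₂ ≤ f₁, f₁+f₂ ≤ Nyquist, with the diagonal
grid restricted to 2f ≤ Nyquist, and T(f, f, f) = E[X(f)³X*(3f)] with
3f ≤ Nyquist.

The 26 parameters follow the fixed table order (1–9 PSD, 10–26
higher-order).  Interpretive conventions, stored as configuration so they
are swappable: spectral moments mₖ = Σ fᵏS(f)/Σ S(f) are taken about zero
with the spectrum as a normalized distribution; threshold counts
("above 0.72 %", …) are relative to that spectrum's own maximum, with a
strict inequality; logarithms use a floor ε = 1e-12 and an all-zero
spectrum yields 0 for every parameter, including the log-sums.  Two rows
of the parameter table are internally inconsistent between description and
formula; the resolutions here are: row 23 counts bispectrum-diagonal bins
above 4.3 % (the description), and row 26 is the 5th moment of the
*trispectrum* diagonal (the formula).  A Hann-windowed STFT magnitude is
provided as a utility for time–frequency inspection and is not part of the
26 features.

Estimator correctness is anchored to independent brute-force oracles
(direct windowed-FFT products on short inputs, direct summation for every
parameter) rather than to any library's higher-order-spectra routine.

## Classifier and experiments

The MLP has one hidden layer, hyperbolic-tangent activations in both
layers, and a 3-unit output with one-hot targets ET = (1,0,0),
PD = (0,1,0), healthy = (0,0,1); prediction is the argmax, ties breaking
toward the lower class index.  Inputs are z-scored with statistics fitted
on training rows only; zero-variance columns map to zeros.  Training is
classic stochastic back-propagation on the squared error: per-sample
updates with a fixed learning rate of 0.01, presentation order reshuffled
each epoch, exactly 200 epochs, weights initialized uniform in
[−0.5, 0.5]/√fan-in — all seeded.  Per-sample updating was chosen over
full-batch descent because at this learning rate the batch variant
converges too slowly to be useful in 200 epochs; the optimizer and rate
are configurable.  Class imbalance is deliberately not corrected — the
error decomposition by pathology exists precisely to expose its effect on
the under-represented ET class.

The three experiment groups select parameters 1–9 (PSD only), 10–26 (HOS
only) or all 26.  A run sweeps hidden sizes 2–10 with 10 seeded
repetitions each and reports the mean validation error and the mean share
of misclassifications attributable to each true pathology.

## Problem sizes and runtime

The shipped checks use the full default cohort (364 train / 156
validation, 20 s recordings), 20 seeds per class for frequency recovery,
the complete 2–10 hidden-size sweep with 10 repeats for the separated
cohort, and single-size (4 hidden units, 10 repeats) runs for the overlap
series — about four minutes end to end on one CPU.

## Known limitations

- The per-test channel reduction (one scalar series per recording) is one
  of several defensible readings; per-axis feature vectors would triple
  the input dimension.
- Unnormalized higher-order spectra make parameters 10–26 scale with the
  signal amplitude cubed/fourth power, so amplitude and nonlinearity are
  entangled exactly as in the parameter table; bicoherence normalization
  is provided only as a sanity check.
- The hand model is a deliberately minimal point mass with a tracking
  controller; it reproduces the direction of force-field effects, not
  limb biomechanics.
- Validation errors on synthetic cohorts are not comparable to clinical
  error rates: real patient recordings are unavailable, and the synthetic
  classes are exactly as separable as the generator makes them.
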