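# Methods

`uwbanthro` implements a noncontact anthropometric measurement pipeline for
impulse-radio ultrawideband (IR-UWB) radar: a physics-based simulator of
multi-sensor recordings of a standing subject, exponential background
subtraction, CA-CFAR height estimation from a ceiling-mounted sensor,
radar-buffer-to-image conversion, and a three-branch late-fusion CNN that
regresses seven anthropometric parameters (height, weight, BMI, muscle %,
skeletal muscle %, body water %, body fat %). This note records the models,
the tunable parameters, and the design choices made where the design was
genuinely open.

## Signal model and simulator

A received frame of sensor *i* at slow-time index *n* is

    x_{i,n}[k] = sum_m A_{m,i,n} S[k - tau_{m,i,n}] + clutter_i[k] + N[k]

with *k* the fast-time (range-bin) index. Defaults follow the measurement
protocol the package targets: center frequency 8.748 GHz, bandwidth
1.5 GHz, receiver sampling 23.328 GS/s (range resolution c/(2 f_s) =
6.43 mm/bin), 20 frames/s, 400 bins/frame, 5 s acquisitions, a
3 m x 3 m x 2.5 m room with one sensor at the ceiling center and two on
opposing walls 1 m above the floor.

Design choices:

* **Pulse template.** A Gaussian-modulated cosine at the carrier
  frequency, with the Gaussian sigma set so the -3 dB power bandwidth
  matches the stated 1.5 GHz; truncated at +-4 sigma (~47 samples). The
  template is kept as an analytic function of continuous sample offset and
  evaluated directly at fractionally shifted positions, so sub-bin delays
  are exact rather than interpolated. The envelope peak sits at offset 0,
  so a path of delay tau puts its echo peak at bin tau and detected peak
  bins map directly to range.
* **Scattering scale.** Echo amplitude grows with body surface area
  (Mosteller: sqrt(height_cm x weight_kg / 3600), normalized to a 1.80 m^2
  reference). The wall sensors, which view the torso, scale linearly in
  BSA; the ceiling sensor views head and shoulders, whose area varies far
  less with body size, and scales as BSA^0.25. The wall/ceiling amplitude
  ratio therefore encodes body size in a way that survives the joint 8-bit
  rescaling of the image stage (which cancels absolute amplitude).
* **Geometry.** The subject stands at the room center; the ceiling sensor
  sees the head at nadir, at range (room height - body height). Wall
  sensors see a fan of seven torso returns at chest height whose extra
  path length spreads across a torso half-width of
  0.17 m x sqrt(BMI / 22.8), so band width in range encodes body width.
* **Body composition.** How composition percentages influence the echo is
  not physically established; the simulator uses an assumed, documented
  linear map — a secondary torso reflection whose amplitude is modulated
  by (+0.008/% muscle, +0.008/% water, -0.006/% fat around the cohort
  medians) — so that all seven regression targets leave a recoverable
  imprint. This coupling is an assumption of the synthetic data, not a
  claim about real radar returns.
* **Micromotion.** Respiration moves the torso surface sinusoidally
  (default 0.25 Hz, 5 mm peak, per-acquisition random phase); the head
  inherits a damped copy (gain 0.25). Without micromotion a standing
  subject would vanish entirely after background subtraction; with it, the
  target survives the clutter filter, which is exactly the mechanism the
  measurement relies on.
* **Noise and clutter.** N[k] is zero-mean white Gaussian (default sd 0.01
  in amplitude units where a reference subject's torso echo is ~1). Static
  clutter is a smooth random per-sensor profile with amplitude ~4, i.e.
  several times the target echo, regenerated deterministically from the
  seed.
* **Cohort sampling.** Heights and BMIs are drawn from truncated normals
  centered on the emulated cohort's medians (height 164.0 cm, BMI 22.8)
  with spreads set from the reported interquartile ranges (IQR/1.349);
  weight is always recomputed as BMI x height_m^2, never sampled, so the
  BMI identity is exact and height-weight correlation is automatic.
  Body-fat percentage co-varies positively with BMI and the muscle/water
  percentages mildly against it. Every stochastic operation is a pure
  function of its seed.

## Background subtraction

The clutter estimate is an exponential moving average with alpha = 0.95:

    C_n[k] = alpha C_{n-1}[k] + (1 - alpha) x_n[k],   y_n[k] = x_n[k] - C_n[k]

The update order is ambiguous in principle (update-then-subtract vs
subtract-then-update); the default updates first, so a step input decays as
y_n = alpha^{n+1} x, and the `legacy_order` flag provides the other
variant. The background is initialized with the first frame (so a static
scene is absent from the residuals immediately); `init="zero"` is available
for analysis. For constant input the residual norm decays exactly
geometrically — the regression tests check the ratio to ~1e-9, the level
where the cancellation x - C (C -> x) exhausts double precision.

## CA-CFAR height estimation

The target envelope is |hilbert(y)| along the range axis of each frame.
The threshold is calibrated per bin from N_c empty-room envelope frames:
T[k] = mu[k] + beta sigma[k] with the per-bin mean and sample standard
deviation (ddof = 1) over the calibration stack. beta defaults to 3.0
(never printed in the protocol this follows); the swapped-symbol variant
T[k] = beta mu[k] + sigma[k] ships behind `convention="literal"`. The
detector reports the smallest bin index starting a run of at least
`min_run` = 2 consecutive bins above threshold.

Height estimation uses the ceiling sensor only. Per frame, the first
threshold crossing gates the head echo; the reported bin is then the
envelope argmax within one pulse-support window (48 bins) after the
crossing. This refinement matters: the envelope of a band-limited pulse
rises over ~2.5 sigma (~15 bins) before its peak, so the raw crossing bin
sits an amplitude-dependent several bins early, while the peak is
amplitude-invariant. `refine=False` restores the raw crossing. Frames with
no detection are dropped (more than 50 % missing aborts with a
diagnostic); the per-frame bins are aggregated by median (or mode), and

    height_cm = (room_height - aggregated_bin x range_resolution) x 100.

Estimates outside (0, room height) are rejected as degenerate geometry. On
simulated 30-subject cohorts this recovers height to within ~1 bin
(max error 0.73 cm, RMSE 0.29 cm with default noise in our runs).

## Imaging

Each acquisition yields three 100 x 400 residual buffers (first 5 s at
20 fps, first 400 bins). The triple is rescaled jointly — one global
min/max across all three sensors — onto 0..255 with round-half-up, so
relative echo strength between sensors is preserved while absolute
amplitude cancels; a constant stack maps to all zeros, and per-sensor
normalization is available behind a flag. The 8-bit matrix is mapped
through a 256-entry colormap (default a jet-like table; grayscale is the
identity ramp) and resized to (227, 227, 3) with bilinear interpolation.
Images remain lossless uint8 arrays end to end and are written as PNG; a
JPEG compatibility path exists but is never used numerically, since a lossy
codec would break bit-level determinism.

## Fusion CNN

One network is trained per anthropometric parameter. Each sensor image
feeds its own branch (weights unshared, since each sensor sees a different
aspect): `depth` blocks of 3x3 valid convolution -> ReLU -> 2x2 average
pooling (stride 2), with `n_filters` filters per layer. The flattened
branch outputs are concatenated (the CAT layer) and passed through one
fully connected layer of width `fc_out` and a single-unit linear regression
head. Architecture defaults follow the stated design (3 hidden conv layers,
filter size 3); the sweep utility covers depth {2, 3} x filters
{16, 32, 64, 128} x FC {256, 512, 1024} on a common split.

Optimization: MSE on z-scored targets, Adam at learning rate 0.001,
minibatch 8, the final partial batch kept. Three numerical choices keep
training stable and are worth recording:

* The CAT vector is scaled by 1/sqrt(d) (d = concatenated length, ~70k at
  default sizes). Without this, any optimizer whose per-weight step is
  roughly magnitude-independent (Adam especially) moves every FC
  pre-activation coherently by ~step x sum|x_i| — tens of z-units per
  update — and training destroys itself in the first few steps.
* The fully connected stage is linear. The ReLU belongs to the convolution
  blocks; a ReLU after the FC layer, fed exclusively all-positive pooled
  features and a shared scalar error signal, collapses to all-dead units
  (we observed exactly this: loss pinned at 1.0 with zero live units).
* Inputs are standardized per branch and channel with training-set
  statistics stored on the model and re-applied at prediction; the raw
  images are dark (mean ~0.2 of full scale), which otherwise shrinks all
  gradients.

Weight initialization is seeded He-style; convolution is im2col + GEMM in
float32 with the patch matrix cached for the backward pass, so the whole
network runs inside BLAS on one CPU.

Dataset splitting is subject-level by default — all repetitions of a
subject land on one side, the leakage-safe choice for recovery
experiments — with the protocol-style random split over individual
acquisitions (which can place repetitions of one subject on both sides)
available as `mode="acquisition"`.

## Agreement statistics

RMSE, MAE, squared Pearson correlation, and ICC(2,1) — two-way random
effects, absolute agreement, single measurement — computed from the ANOVA
mean squares of the n x 2 table:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n),  k = 2.

Absolute agreement is the appropriate variant for comparing two measurement
methods because it penalizes systematic bias. Variance-based statistics use
sample (n-1) denominators. For exactly identical vectors the report returns
ICC = r^2 = 1 by convention.

## What the synthetic data does and does not show

The simulator reproduces the *mechanisms* the pipeline exploits — geometry
-> head range, micromotion -> clutter-filter survival, body size -> echo
amplitude/band width, composition -> a documented amplitude modulation — in
a controlled, seeded way. It does not reproduce real antenna patterns,
multipath off walls and furniture, posture variability, clothing, or the
true (unknown) physical coupling between body composition and skin
reflectivity. Passing recovery tests therefore demonstrates that the
implementation is correct and that the method can extract the encoded
information; it does not certify clinical accuracy on real subjects, and
the published clinical agreement values are deliberately not used as
targets here.

## Problem sizes used in tests and the acceptance script

Simulation-recovery experiments run at sizes chosen to exercise the method
on a single CPU: height recovery on 30-subject cohorts with a 30 s
(600-frame) calibration; CNN weight recovery on 60 subjects x 8 repetitions
with a compact architecture (depth 2, 8 filters, FC 128) and 20 epochs; the
architecture sweep smoke test runs the full grid on small synthetic images.
Seeds are fixed throughout; rerunning any experiment with the same seed is
bit-reproducible.
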