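# uwbanthro

Noncontact anthropometric measurement from multi-sensor IR-UWB radar.

Impulse-radio ultrawideband (IR-UWB) radar transmits sub-nanosecond pulses
and samples the returning echoes at fine range resolution (6.4 mm/bin at
23.328 GS/s). A person standing in a room leaves a characteristic imprint
in those echoes: the ceiling-to-head range gives height directly, and the
strength and spread of the torso return grow with body size. `uwbanthro`
implements the full measurement chain for a three-sensor room (one sensor
at the ceiling center, two on opposing walls) and is aimed at researchers
in biomedical radar sensing who want a reproducible, fully synthetic
test bed for the method:

1. **Simulation** (`signal_sim`) — the received frame is modeled as
   `x_{i,n}[k] = Σ_m A_{m,i,n} S[k − τ_{m,i,n}] + clutter_i[k] + N[k]`,
   with path delays from room geometry, amplitudes from a body-surface-area
   scattering proxy, respiratory micromotion, static clutter and white
   noise. Cohorts are sampled around realistic anthropometric medians
   (height 164 cm, BMI 22.8), fully seeded.
2. **Preprocessing** (`preprocess`) — exponential background subtraction
   `C_n = αC_{n−1} + (1−α)x_n`, `y_n = x_n − C_n` with α = 0.95, and
   Hilbert-envelope extraction along the range axis.
3. **Height estimation** (`cfar_height`) — a CA-CFAR threshold
   `T[k] = μ[k] + βσ[k]` calibrated from empty-room envelope statistics;
   per-frame first-crossing detection refined to the echo peak;
   `height = room_height − detected_range`.
4. **Imaging** (`imaging`) — 100×400 residual buffers from the three
   sensors, jointly rescaled to 8 bits, colormapped to RGB and resized to
   (227, 227, 3).
5. **Regression** (`fusion_cnn`) — a three-branch late-fusion CNN (per
   sensor: conv 3×3 → ReLU → average pool, branches concatenated at the
   CAT layer, one FC layer, scalar regression head), one network per
   anthropometric parameter, trained with Adam at lr 0.001, minibatch 8.
   Pure numpy, single-CPU.
6. **Agreement statistics** (`metrics`) — RMSE, MAE, Pearson r², and
   ICC(2,1) (two-way random effects, absolute agreement) from ANOVA mean
   squares.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import uwbanthro as u

subject = u.SubjectProfile.from_height_weight(171.0, 68.0)
geometry, pulse = u.RoomGeometry(), u.PulseModel()

empty = u.simulate_empty_room(geometry, pulse, duration_s=30.0, seed=2)
calib = u.CalibrationBuffer.from_recording(u.subtract_background(empty), sensor=0)
threshold = u.calibrate_threshold(calib, beta=3.0)

rec = u.simulate_session(subject, geometry, pulse, seed=3)
est = u.estimate_height(u.subtract_background(rec), threshold,
                        room_height=geometry.height,
                        sampling_rate=pulse.sampling_rate)
print(est.height)
```

Running `python examples/02_height_from_ceiling_sensor.py` (the same
computation with commentary) prints:

```
true height      : 171.0 cm
estimated height : 171.6 cm
detected range   : 0.784 m (bin 122, 94 frames used)
error            : +0.61 cm (0.9 range bins)
```

i.e. the CFAR detector locates the head echo to within about one 6.4 mm
range bin, and the height follows from the known ceiling height. The other
examples cover cohort simulation (`01`), CNN weight regression on a
held-out subject split (`03`), and the agreement statistics (`04`).

A thin CLI mirrors the pipeline stages
(`uwbanthro simulate|preprocess|height|make-images|train|predict|evaluate|run-all`);
recordings are stored as HDF5 (`/sensor{i}/frames` plus `fps`, `seed`,
`sensor_ids`, `subject` attributes), cohorts and reports as CSV, model
metadata as JSON.

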