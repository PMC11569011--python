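# Methods

## Measurement model

Each sensor is a tri-axial accelerometer sampled at 128 Hz. At rest it
measures the gravity reaction, a unit vector in the sensor frame, so
segment inclination relative to the vertical follows from pure
projection — no gyroscope integration, hence no drift accumulation.

Axis conventions are fixed by the package (and emitted by the
simulator): trunk sensors carry +x along the cranial axis, so upright
stance reads a_x = −1 g and the inclination is
−arctan(√(a_y² + a_z²)/a_x); leg sensors are mounted so anterior tilt
drives a_y negative, giving the signed inclination
−arctan(a_y/√(a_x² + a_z²)). Both are implemented with the two-argument
arctangent so that a horizontal sensor returns exactly 90° rather than
dividing by zero; the printed formulas are recovered on their principal
range. A per-sensor sign-flip switch accommodates real hardware mounted
differently.

The trunk inclinations are inclinations to the vertical, not projections
onto the sagittal plane: lateral and oblique lean contribute, by design.

### Perpendicular method

CA_per = 0.3856 + 0.4542·φ_L5 + 0.5458·φ_C7 (all degrees). The affine
form comes from treating the spine as a flexible chain of vertebrae with
fixed height and mobility distribution; the coefficients sum to one, so
a rigid-trunk rotation by α maps to CA_per = α + 0.3856. The model's
validity for strongly negative or very large inclinations is not
established; the package flags |CA_per| > 90° as suspicious rather than
guarding further.

### Malleolus method

The leg is modelled as two coupled pendula rotating in the sagittal
plane: knee angle θ = 180° − φ_TH − φ_SH (interior angles of the two
triangles each segment forms with the vertical), vertical drops
Z_u = u·cos φ_TH and Z_l = l·cos φ_SH, hip–ankle distance H from the
cosine law, and leg angle magnitude arccos((Z_u + Z_l)/H). The sign is
that of the ankle's anterior offset u·sin φ_TH − l·sin φ_SH — positive
when the foot is in front of the frontal plane. CA_mal = CA_per + Φ_leg
holds exactly at every sample of an uncalibrated series.

Numerically the signed angle is computed as
atan2(u·sin φ_TH − l·sin φ_SH, Z_u + Z_l), which is algebraically
identical (H is the norm of that vector) but keeps full precision near
the straight vertical leg, where the arccos argument approaches 1 and
would lose half the significant digits. The arccos argument is still
formed for a consistency check: values beyond 1 + 1e-9 mark the sample
physically invalid, as does a knee angle outside (0°, 180°]. Invalid
samples propagate as masks; they are never dropped, keeping all series
sample-aligned.

Out-of-plane leg motion is model error by construction (the planar
simplification is deliberate); walking therefore shows the largest leg
errors, concentrated in the swing phase.

## Preprocessing

Raw channels are smoothed with a third-order Savitzky-Golay filter.
The window length is a free parameter; the default is 1.0 s (129
samples at 128 Hz), matching the one-second windows used for reporting
and suppressing gait-frequency noise while keeping posture transitions.
Edges are handled by fitting the polynomial to the truncated first/last
window and evaluating it there (scipy's `mode="interp"`), so
polynomials of degree ≤ 3 pass through exactly and nothing is padded
with zeros.

A confidence mask flags samples whose acceleration magnitude leaves the
closed band [0.5, 1.5] g (near-free-fall, impacts): gravity projection
is meaningless there. Flagged samples are masked, not removed.

## Calibration

* **Zero calibration**: per-channel mean inclination over a 60-s
  upright standing window becomes the zero reference and is subtracted
  from the subsequent recording. Windows shorter than 5 s, outside the
  recording, or more than half masked are rejected.
* **Patient-specific calibration**: the IMU CA_per and CA_mal averaged
  over a standing-forward-lean window are compared with the two angles
  measured manually from a photograph of the same posture; the
  differences (photo − measured) are added to the respective CA streams
  thereafter. By construction the calibration posture then reads the
  photo value exactly.
* **offset_leg**: the leg angle referenced at L5 (the camptocormia
  convention) differs from the hip-axis-referenced angle the leg
  sensors actually measure, because L5 sits posterior and superior to
  the hip's rotation axis. The gap is nearly constant over the relevant
  posture range; it is estimated as the mean difference between the two
  marker-derived leg references over a static window and *added* to the
  hip-referenced IMU leg angle to express it in the L5 frame. (Adding,
  not subtracting, is the geometrically consistent direction: for a
  perfectly upright body the IMU reads 0° while the L5–malleolus line
  already makes a positive angle with the vertical.) offset_mal and
  offset_leg address the same anatomical discrepancy through different
  routes, so applying both to one CA_mal stream is rejected at run time.

## Reference reconstruction

Reference angles come from four optical markers (C7, L5, iliac crest
IC, lateral malleolus LM) in a ground frame with z vertical: the trunk
reference is the angle of the L5→C7 displacement against the vertical,
the leg references are the absolute angles of LM→L5 and LM→IC, and the
reference malleolus angle is their sum with the trunk term. All three
are computed on coordinate *differences*: a segment direction must be
invariant under translation of the capture volume's origin, and only
displacement differences are. The leg references are unsigned
(absolute value), whereas the IMU leg angle is signed; near-zero leg
angles therefore compare a signed estimate against a folded reference —
a known convention mismatch that matters only within noise of 0°.

Marker streams are linearly resampled to the IMU rate before
comparison; a configurable time offset covers manual stream alignment,
since no hardware synchronization is assumed.

## Evaluation

Estimator and reference are compared on one-second non-overlapping
window means (sample-wise on request). Windows anchor at activity
segment starts; a window mean uses only unmasked samples, a fully
masked window is masked, and a partial trailing window is kept when at
least half of it is unmasked — short segments (the 25-s walking block)
would otherwise lose data. Per-activity RMSE pools every window of that
label; the overall figure pools all labeled windows, so overall RMSE²
is exactly the window-count-weighted mean of the per-activity RMSE².
The MAD histogram bins |estimate − reference| by the reference angle
rounded to the nearest whole degree, rounding half away from zero.

## Synthetic data generator

The generator inverts the measurement models. A posture script
prescribes, per labeled activity block, the true trunk flexion
CA_per(t), leg angle Φ_leg(t) and knee flexion κ(t) as constants, ramps
or sinusoids. Spine truths solve the affine trunk model under a
configurable distribution ratio φ_C7 = r·φ_L5 (default r = 1; any pair
satisfying the model is a valid truth). Leg truths use the closed form
φ_TH = Φ_leg + atan2(l·sin κ, u + l·cos κ), φ_SH = κ − φ_TH, obtained
by factoring the two-segment chain as u·e^{iφ_TH} + l·e^{i(φ_TH−κ)};
the forward model then reproduces Φ_leg exactly.

Accelerometer channels are the unit gravity vector rotated into each
sensor frame plus white noise (default σ = 0.02 g, consumer-grade IMU
noise with mild soft-tissue vibration) and optional motion-artifact
bursts. Markers ride on the same body model: the hip pivot is fixed,
the ankle hangs from the two-pendulum leg, IC sits on the hip axis, and
L5 sits 0.117 m posterior and 0.05 m superior to it — which produces an
offset_leg of about 7° for a 0.9-m leg, the magnitude reported for this
marker arrangement in practice. Marker jitter defaults to 0.5 mm. All
randomness flows from one explicit seed; identical seeds give
bit-identical output.

Consecutive blocks are blended with a cosine ease (default 1 s, 2 s in
the bundled study script) because a subject moves continuously between
activities; the blend modifies the truth itself, so it costs no
closed-loop accuracy.

The bundled `default_study_script` mirrors a four-minute laboratory
session — 60 s upright (8° habitual trunk angle), 50 s forward lean
(40° trunk, 8° leg), 25 s walking (±15° leg swing at 1 Hz cadence),
80 s stooped small-stride gait (35° trunk, ±8° leg at 0.8 Hz). A
`quasistatic_study_script` variant keeps the same labeled 60/50/25/80-s
structure but restricts all trajectories to ≤ 0.1 Hz; within the 1-s
cubic filter window such signals are locally polynomial, so this script
verifies the full angle-computation chain end to end at numerical
precision (closed-loop RMSE below 0.01°), isolated from the filter's
finite bandwidth.

### What the generator does not emulate

Soft-tissue artifact beyond additive bursts, sensor mounting
misalignment, out-of-plane (abduction/rotation) leg motion, ground
contact and double support in gait, marker occlusion. Passing
closed-loop tests therefore demonstrates correctness of the angle
algebra, the calibration arithmetic and the evaluation statistics under
the stated noise model — not the field accuracy of the sensor method on
a real body, where skin movement and model mismatch dominate.

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| sample rate | 128 Hz | native sensor rate |
| SG order / window | 3 / 1.0 s | order fixed by the method; window matches the 1-s reporting windows |
| confidence band | [0.5, 1.5] g | excludes free-fall/impact where gravity is unreadable |
| zero-calibration window | 60 s | averaging time for the upright reference |
| camptocormia cutoff | 30° (strict >) | consensus definition on CA_mal |
| arccos guard | 1e-9 | beyond it the sample is flagged, not silently clamped |
| thigh/shank lengths | 0.45 / 0.45 m | adult anthropometry; always user-supplied in practice |

## Known limitations

The perpendicular model's affine coefficients embed a specific spinal
mobility distribution; extreme kyphosis may violate it. The malleolus
chain ignores pelvis rotation, which moves L5 around the hip axis and
bends the "constant offset" assumption during dynamic activity. The
smoothing filter's ~1 Hz bandwidth trades gait-noise suppression
against attenuation of genuine fast posture change; for gait-phase
analysis a shorter window should be configured. Activity segments are
taken from an annotation file; automatic activity recognition is out of
scope.
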