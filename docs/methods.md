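# Methods

## Model

The neck is modeled as a rigid stick of length `l12` between two ball
joints: `J1` near vertebra C7 and `J2` near vertebra C2.  `J2` is the head
center.  Each joint has three rotational degrees of freedom, but rotation
about the stick axis is common to both, so the head moves with five degrees
of freedom relative to the thorax; translation along the spinal axis is
neglected (it is a few millimeters in vivo).  The stick direction is the
y-axis (cranial axis) of the neck rigid body's calibrated orientation.

For identification the model is extended by two constant lever arms:
`vs1` from the sternum marker-cluster origin to `J1` (constant in the
sternum frame) and `v2h` from `J2` to the forehead cluster origin (constant
in the head frame).  The predicted forehead position in the sternum frame,

    o_hat = vs1 + l12 * (Rs^T Rn) e_y + (Rs^T Rh) v2h,

is linear in the seven unknowns `(vs1, l12, v2h)`; all trials of a
participant are pooled into one least-squares system, solved by SVD.

### Axis and sign conventions

* Axes: x lateral, y cranial (up at the upright posture), z anterior;
  right-handed.  Internally meters and radians; millimeters and degrees at
  every reporting surface.
* The thorax-fixed "up" (head-pointing) vector used for protraction is the
  **y-column** of the calibrated sternum orientation.  This is forced by
  consistency: the stick occupies the neck body's y-axis, calibration makes
  all orientations identity at the upright posture, and protraction must
  vanish there.  Defining "up" as the z-column instead would make stick and
  up-vector orthogonal at calibration and yield `p = l12` for an upright
  posture, which is not a usable definition; the z-column and a space-fixed
  vertical remain available as options (`up_axis="z" | "earth"`).
* Two protraction quantities exist and differ for nonzero angles: the
  scalar `p = l12*sin(phi)` (norm of the stick component orthogonal to the
  up vector) and the vector `p_e = v12 - l12*u` (whose norm is
  `2*l12*sin(phi/2)`).  Both are exposed; the scalar follows the
  orthogonal-component definition.
* Residual sign: predicted minus measured, so negative mean errors are
  under-predictions.
* The frame-change helper `transform_point` applies `R v - o` (the origin
  subtracted after rotation).  Poses constructed from data (marker fits,
  files, the simulator) store the plain position of the body origin in the
  parent frame, which is how origins enter the measured head position
  `Rs^T (o_h - o_s)`; the two conventions are documented side by side in
  `frames.py`.

### Calibration

Each body's orientation series `R(t)` is composed with the transpose of its
chordal-mean orientation over a static upright window:
`R~(t) = R(t) * mean(R(t0..t1))^T`.  This is the rotation of the body since
the calibration posture expressed in lab axes — a common frame for all
bodies — and is exact for arbitrary tripod mounting (verified in tests by
mounting tripods at large arbitrary rotations and recovering the model
parameters to machine precision).  The chordal mean (arithmetic mean of
matrices projected onto SO(3) via the orthogonal polar factor) is accurate
for the sub-degree spreads of a genuinely static window; a spread above a
configurable threshold (default 2 deg) logs a warning.  The earth frame is
taken to coincide with the lab frame up to a fixed configurable rotation
(identity by default): optical data never observe magnetic north.

### Euler angles

Reported rotations use an intrinsic sequence with lateral inclination as the
intermediate angle (default `XZY`: flexion/extension, lateral inclination,
axial rotation).  Lateral inclination stays far below 90 degrees for
physiological neck motion, so the decomposition cannot reach gimbal lock;
an intermediate angle within 1e-6 rad of 90 degrees raises an error rather
than returning garbage.

## Identification

* Solver: SVD-based minimum-norm least squares; numerical rank uses a
  relative singular-value cutoff of 1e-10.  Rank below 7 raises an
  identifiability error naming the unexcited parameter directions (from the
  right singular vectors); purely static data fail this way.  The
  normal-equations solution is kept as an independent test oracle, never as
  the implementation.
* Residual summaries: per-axis mean error plus 5%/95% percentiles (linear
  interpolation between order statistics), in millimeters.
* A pooled fit's per-axis mean residuals are exactly zero by construction:
  the `vs1` columns are per-axis intercepts, and least-squares residuals
  are orthogonal to them.  Accuracy tables therefore report per-trial mean
  errors under the pooled fit, which measure how well one parameter set
  transfers across movement tasks.
* Percentile convention, residual sign and pooling (all trials of a
  participant in one fit; per-trial fitting available for diagnostics) are
  package choices where no single convention is canonical.

## Anthropometric length model

`l12 = beta1 * lC2C7 + beta0`, ordinary least squares with intercept across
participants; `residual_sd` is the regression standard error
(`sqrt(SS_res/(n-2))`).  Units are converted at the file boundary (palpated
lengths in cm); the API is meters.  The parametrized-model validation
replaces only `l12` by the prediction (lever arms unchanged) and compares
head-center (`J2`) trajectories against the fitted model; since `J2` is
linear in `l12`, the per-sample difference is exactly the length error along
the instantaneous stick direction, and the induced protraction error is
proportional to the true protraction.

## Synthetic data generator

The generator is the package's test bed and defines the study conditions:

* Tasks: zigzag and cross patterns as piecewise minimum-jerk joint-angle
  waypoint trajectories (three repetitions per trial), each in neutral and
  protracted head position; band-limited random free movement (sum of four
  random-phase sinusoids below 0.4 Hz per axis); static sitting.  120 Hz
  sampling.  Every trial starts with a 1 s neutral static lead-in that
  serves as its calibration window.
* Amplitudes: ±30 deg flexion/extension, ±20 deg lateral inclination, with
  axial rotation coupled to lateral bending (0.4 of the normalized lateral
  channel times a ±15 deg amplitude), all configurable and bounded by
  physiological limits (80/45/80 deg).  The protracted offset is 25 deg,
  ramped in over 1 s and held.  Amplitudes and offset are package fixtures
  chosen as physiologically plausible, not measured values.
* Movement distribution: `thorax_share` splits the target rotation between
  the thorax and the neck joint (default 0), emulating participants who
  move with their upper thorax; `head_share` (default 0.4) is the fraction
  of the gaze rotation contributed by the upper cervical spine.
* Markers: three-marker equilateral tripods of 5 cm side (configurable), an
  optional mounting rotation per tripod, and iid Gaussian marker noise
  (default SD 0.1 mm, a typical optoelectronic precision).  Orientation
  noise composes random rotations with uniform axis and half-normal angle.
* Cohorts: anthropometrics are Gaussian draws (truncated at ±3 SD) matching
  the packaged reference table's means and SDs; true stick lengths follow
  `l12 = 1.2 * lC2C7 + 45 mm` plus 8 mm Gaussian scatter by default, and
  lever arms are jittered around anatomy-plausible defaults
  (`l12` 120 mm, `vs1` = (0, 100, -80) mm, `v2h` = (0, 60, 90) mm).

What the generator does **not** emulate: soft-tissue artifact, marker
occlusion and relabeling, spinal axial translation, trial-to-trial
re-mounting, and the laser/wall geometry of pursuit tasks (joint angles are
parameterized directly).  Passing tests on synthetic data therefore
demonstrate the correctness and noise behaviour of the algorithms under the
model's own assumptions, not the model's physiological adequacy.

## Noise sweep

Position and/or orientation noise is injected into clean simulated trials
at 1x/5x/10x base levels (defaults 0.1 mm / 0.1 deg), the full
pose-recovery -> calibration -> identification pipeline re-runs, and the
distribution of the re-estimated length over 25 repetitions is summarized.
Common random numbers (the same standard draws, scaled) are shared across
multipliers and variants per repetition, making the monotone growth of the
orientation-noise bias testable with few repetitions.

Two findings worth recording:

* Orientation noise attenuates the length estimate (errors-in-variables in
  the stick-direction regressor), so the bias is negative and grows with
  the noise level.  The effect size depends strongly on excitation
  richness: if the sweep battery omits the protracted tasks, the neck and
  head angle series are exactly proportional (constant `head_share`), the
  design matrix becomes near-collinear, and the shrinkage grows by an order
  of magnitude.  The sweep therefore always takes a participant's full
  battery, and richer excitation is the practical remedy.
* Position noise is unbiased at the base level, but at 10x (1 mm on a 5 cm
  tripod) the rigid-body fit converts it into ~2 deg of orientation noise,
  which biases the length just like direct orientation noise.
  "Position noise is harmless" is a statement about the measurement noise
  floor, not about position noise per se.

## Problem sizes and runtime

Default analysis runs use 4–8 subjects, 12 s pattern trials, 30 s free
movement and 25 sweep repetitions; the test suite shortens trials to 2–8 s,
which leaves every qualitative result unchanged while keeping the whole
suite under a minute.  All randomness flows from a single master seed via
spawned seed sequences, and identical seeds reproduce every output byte for
byte.

## Known limitations

* The model ignores spinal translation and assumes truly rigid
  marker-to-bone coupling; both are violated to some degree in vivo.
* The anthropometric predictor is deliberately simple (one linear term);
  its residual scatter translates into proportional protraction errors.
* The calibration assumes the participant actually holds an upright static
  posture in the window; the spread warning is the only guard.
* Identifiability rests on excitation richness; near-proportional neck and
  head motion inflates both variance and noise-induced bias of the length
  estimate even when the system is formally rank 7.
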