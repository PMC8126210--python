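# neckstick

Two-joint neck kinematics: 3-D head position and protraction relative to the
thorax from two rigid-body orientations.

## The problem

Prolonged forward head posture (protraction of the head relative to the
thorax) is associated with neck pain and headache, and could be prevented
with posture biofeedback — if protraction could be measured with a simple
sensor setup.  Camera-based motion capture measures it accurately but is
stationary and expensive; plain orientation sensors measure angles but not
the translation that defines forward head posture.

`neckstick` implements a minimal biomechanical model that closes this gap:
the neck is a stiff stick of length $l_{12}$ between two ball joints,
$J_1$ near vertebra C7 and $J_2$ near vertebra C2.  $J_2$ defines the head
center, so the position of the head relative to the thorax is determined by
just **two orientations** — thorax and neck — plus one length.  Rotation
about the stick axis is shared by both joints, leaving five degrees of
freedom; translation along the spine (a few millimeters at most) is
deliberately ignored.

The package is aimed at movement scientists and biomechanical engineers who
want to identify the model from marker-based motion capture, quantify
protraction, and understand how measurement noise and anthropometric
shortcuts degrade the estimate.

## The model

With calibrated orientations (identity at the upright reference posture),
the predicted forehead-cluster position in the sternum frame is

$$\hat o_h^s = v_{s1}^s + l_{12}\,(R_s^\top R_n)\,e_y + (R_s^\top R_h)\,v_{2h}^h$$

where $e_y = (0,1,0)^\top$ is the cranial axis of the neck body (the stick
direction), $v_{s1}$ is the constant lever arm from the sternum cluster to
$J_1$, and $v_{2h}$ the constant lever arm from $J_2$ to the forehead
cluster.  The measured counterpart is $\tilde o_h^s = R_s^\top(o_h - o_s)$.
The prediction is **linear** in the seven unknowns
$\theta = (v_{s1}, l_{12}, v_{2h})$, so pooling all trials of one
participant gives one overdetermined linear system solved in a single step
(rank-revealing SVD).

Protraction follows from the identified length alone:
$p = l_{12}\sin\varphi$, with $\varphi$ the angle between the stick and the
thorax-fixed up vector; a mis-specified length scales the protraction
estimate — and hence its error — proportionally.

Because a participant's own $l_{12}$ requires a one-off identification
session, the package also fits the anthropometric fallback
$l_{12} = \beta_1\, l_{C2C7} + \beta_0$ across a cohort from the palpable
C2–C7 distance, and quantifies what that substitution costs.

A synthetic motion-capture simulator (laser-pursuit-style zigzag/cross
tasks, protracted-posture variants, free movement, three-marker tripods,
configurable marker and orientation noise) provides ground truth for every
stage, and a Monte-Carlo noise sweep reproduces the estimator's
noise-sensitivity structure: orientation noise biases the length estimate
toward shorter sticks, position noise at the measurement floor does not.

## Worked example

`examples/01_simulate_and_fit.py` simulates one participant's task battery
(static sitting, zigzag and cross in neutral and protracted head position,
free movement) at 120 Hz with 0.1 mm marker noise, calibrates each trial on
its static lead-in, and identifies the seven parameters:

```
true neck-stick length :  120.00 mm
fitted                  :  120.07 mm
thorax lever arm error  :  0.0620 mm
head lever arm error    :  0.0740 mm
condition number        :    13.7
residual x: ME  -0.0000 mm   5%/95%:  -0.7931 /  +0.8032 mm
residual y: ME  -0.0000 mm   5%/95%:  -0.5960 /  +0.6022 mm
residual z: ME  -0.0000 mm   5%/95%:  -0.7767 /  +0.7663 mm
```

The fitted length lands within a tenth of a millimeter of the truth; the
5%/95% residual percentiles show the sub-millimeter spread that marker noise
leaves after the model has absorbed the motion; the per-axis mean errors of
a pooled fit are zero by construction (the lever-arm columns act as
intercepts), so per-trial mean errors are the meaningful accuracy measure.

The other examples cover protraction monitoring (`02`), the anthropometric
length model and its accuracy cost (`03`), the noise sweep (`04`), and the
full pipeline with all artifacts (`05`).  The same functionality is exposed
as a thin CLI: `neckstick simulate | calibrate | fit | length-model |
validate | protraction | noise-sweep | pipeline`.

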