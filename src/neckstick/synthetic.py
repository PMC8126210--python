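"""Synthetic motion-capture generator for the two-joint neck model.

Generates ground-truth neck/head/thorax orientation trajectories realizing
laser-pointer-style pursuit tasks (zigzag and cross patterns in neutral or
protracted head position, band-limited free movement, static sitting),
computes exact marker positions of the three tracked tripods through the
forward model, and adds configurable Gaussian marker and orientation noise.
Ground truth — poses and the seven model parameters — is retained alongside
the "measured" data, so every downstream stage (pose recovery, calibration,
identification, noise sweeps) can be validated against construction.

The tasks are parameterized directly as joint-angle trajectories (minimum-
jerk transitions between pattern waypoints) rather than through the wall and
laser geometry: only the orientation/position time series matter to the
model.  Each trial starts with a short neutral, static lead-in that serves
as its calibration window.

A "movement distribution" knob (``thorax_share``) splits each target
rotation between the thorax and the neck joint, emulating participants who
move with their upper thorax rather than the cervical spine alone; the
``head_share`` knob sets the fraction of gaze rotation contributed by the
upper cervical spine (head on neck).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .anthropometry import ParticipantAnthro
from .frames import rotation_from_euler
from .model import NeckParameters
from .recording import PoseSeries, TrialRecording, recover_poses

BODIES = ("head", "sternum", "neck")

#: Physiological amplitude ceilings, radians (flexion/extension, lateral
#: inclination, axial rotation).
MAX_AMPLITUDES = tuple(np.radians([80.0, 45.0, 80.0]))

#: Default anatomy-plausible model parameters (meters): stick length 12 cm,
#: sternum cluster to C7 joint, C2 joint to forehead cluster, in the
#: x-lateral / y-cranial / z-anterior axes.
DEFAULT_PARAMS = NeckParameters(
    l12=0.12, vs1=(0.0, 0.10, -0.08), v2h=(0.0, 0.06, 0.09)
)

#: Reference-cohort statistics used by :func:`generate_cohort`:
#: (mean, sd) per column of the packaged anthropometrics table.
COHORT_STATS = {
    "length_C7S2_cm": (50.7, 2.2),
    "length_C2C7_cm": (5.8, 0.9),
    "height_m": (1.73, 0.09),
    "bmi": (24.0, 2.4),
    "age_y": (41.1, 11.9),
}


def equilateral_reference_geometry(side: float = 0.05) -> np.ndarray:
    """Marker triplet of a tripod: equilateral triangle, centered, local x-y plane."""
    r = side / np.sqrt(3.0)
    ang = np.radians([90.0, 210.0, 330.0])
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)])


@dataclass(frozen=True)
class TaskSpec:
    """One movement task.

    ``pattern`` is one of ``zigzag | cross | free | static``;
    ``head_position_mode`` is ``neutral`` or ``protracted`` (a sustained
    forward-head offset held throughout the pattern).  Amplitudes are
    radians per rotation axis and must stay within physiological bounds.
    Pattern tasks repeat their figure ``repetitions`` times (three by
    default) within ``duration_s``.
    """

    pattern: str
    head_position_mode: str = "neutral"
    repetitions: int = 3
    duration_s: float | None = None
    amplitude_flexion: float = np.radians(30.0)
    amplitude_lateral: float = np.radians(20.0)
    amplitude_axial: float = np.radians(15.0)

    def __post_init__(self):
        if self.pattern not in ("zigzag", "cross", "free", "static"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.head_position_mode not in ("neutral", "protracted"):
            raise ValueError(f"unknown head position mode {self.head_position_mode!r}")
        amps = (self.amplitude_flexion, self.amplitude_lateral, self.amplitude_axial)
        for a, bound, name in zip(amps, MAX_AMPLITUDES, ("flexion", "lateral", "axial")):
            if not 0 <= a <= bound:
                raise ValueError(
                    f"{name} amplitude {np.degrees(a):.1f} deg outside physiological "
                    f"range [0, {np.degrees(bound):.0f}] deg"
                )
        if self.duration_s is None:
            default = {"zigzag": 12.0, "cross": 12.0, "free": 30.0, "static": 5.0}
            object.__setattr__(self, "duration_s", default[self.pattern])

    @property
    def label(self) -> str:
        if self.pattern in ("zigzag", "cross"):
            return f"{self.pattern}_{self.head_position_mode}"
        return self.pattern


def standard_task_set(free_duration_s: float = 30.0) -> list[TaskSpec]:
    """The study-style task battery: static sitting, zigzag and cross in both
    head positions, and free movement."""
    return [
        TaskSpec("static"),
        TaskSpec("zigzag", "neutral"),
        TaskSpec("zigzag", "protracted"),
        TaskSpec("cross", "neutral"),
        TaskSpec("cross", "protracted"),
        TaskSpec("free", duration_s=free_duration_s),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a simulated trial depends on besides the task itself.

    ``marker_noise_sd`` defaults to 0.1 mm, a typical optoelectronic marker
    precision; ``protraction_offset`` (25 deg) is the sustained forward-head
    angle of protracted tasks.  Both are package fixtures, not measured
    values.  ``mounting`` optionally rotates each tripod's local axes
    relative to the body's calibrated axes, to exercise the calibration
    stage; identity by default.
    """

    true_params: NeckParameters = DEFAULT_PARAMS
    anthro: ParticipantAnthro | None = None
    sample_rate: float = 120.0
    marker_noise_sd: float = 1e-4
    orientation_noise_sd: float = 0.0
    seed: int = 0
    thorax_share: float = 0.0
    head_share: float = 0.4
    protraction_offset: float = np.radians(25.0)
    lead_in_s: float = 1.0
    reference_side: float = 0.05
    mounting: dict | None = None

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.marker_noise_sd < 0 or self.orientation_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0.0 <= self.thorax_share < 1.0:
            raise ValueError("thorax_share must be in [0, 1)")


@dataclass
class SimulatedTrial:
    """A simulated recording plus its generating truth."""

    recording: TrialRecording  # markers (noisy if configured) + poses recovered from them
    truth: TrialRecording      # exact calibrated poses, noise-free
    params: NeckParameters
    task: TaskSpec
    config: SimulationConfig


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp with zero velocity and acceleration at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


_ZIGZAG = [(0, 0), (1, -1), (-1, -0.5), (1, 0), (-1, 0.5), (1, 1), (0, 0)]
_CROSS = [(0, 0), (1, 0), (-1, 0), (0, 0), (0, 1), (0, -1), (0, 0)]


def _waypoint_angles(waypoints, repetitions: int, t: np.ndarray, duration: float) -> np.ndarray:
    """Piecewise minimum-jerk interpolation through (flex, lat) waypoints."""
    pts = np.asarray(list(waypoints) + list(waypoints[1:]) * (repetitions - 1), dtype=float)
    n_seg = len(pts) - 1
    seg_dur = duration / n_seg
    out = np.zeros((len(t), 2))
    idx = np.minimum((t / seg_dur).astype(int), n_seg - 1)
    u = t / seg_dur - idx
    s = minimum_jerk(u)
    out = pts[idx] + (pts[idx + 1] - pts[idx]) * s[:, None]
    return out


def _free_angles(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Band-limited random angles, one normalized channel per axis."""
    out = np.zeros((len(t), 3))
    for i in range(3):
        coeff = rng.normal(size=4)
        freqs = rng.uniform(0.05, 0.4, size=4)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        sig = np.sum(coeff[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]),
                     axis=0)
        peak = np.max(np.abs(sig))
        out[:, i] = 0.8 * sig / peak if peak > 0 else 0.0
    # ease in from rest over the first two seconds
    out *= minimum_jerk(t / 2.0)[:, None]
    return out


def task_angle_series(task: TaskSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaze target angles (flexion, lateral, axial), radians, over task time ``t``."""
    amps = np.array([task.amplitude_flexion, task.amplitude_lateral, task.amplitude_axial])
    if task.pattern == "static":
        return np.zeros((len(t), 3))
    if task.pattern == "free":
        return _free_angles(t, rng) * amps
    waypoints = _ZIGZAG if task.pattern == "zigzag" else _CROSS
    fl = _waypoint_angles(waypoints, task.repetitions, t, task.duration_s)
    angles = np.zeros((len(t), 3))
    angles[:, 0] = fl[:, 0] * amps[0]
    angles[:, 1] = fl[:, 1] * amps[1]
    # lateral bending couples with axial rotation in the cervical spine
    angles[:, 2] = 0.4 * fl[:, 1] * amps[2]
    return angles


def _euler_series(angles: np.ndarray) -> np.ndarray:
    """Batch of rotation matrices from (n, 3) intrinsic XZY angle rows."""
    return Rotation.from_euler("XZY", angles[:, [0, 1, 2]]).as_matrix()


def simulate_trial(task: TaskSpec, config: SimulationConfig) -> SimulatedTrial:
    """Simulate one trial: smooth task kinematics -> exact markers -> noise.

    The trial timeline is ``lead_in_s`` of neutral upright stillness (the
    calibration window) followed by the task.  In protracted mode a constant
    forward-head offset (neck flexed anteriorly, gaze unchanged) ramps in
    over the first second of the task and is held throughout.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate
    n_lead = int(round(config.lead_in_s * config.sample_rate))
    n_task = int(round(task.duration_s * config.sample_rate)) + 1
    time = np.arange(n_lead + n_task) * dt
    t_task = np.arange(n_task) * dt

    theta = np.zeros((len(time), 3))
    theta[n_lead:] = task_angle_series(task, t_task, rng)

    offset = np.zeros(len(time))
    if task.head_position_mode == "protracted":
        offset[n_lead:] = config.protraction_offset * minimum_jerk(t_task / 1.0)

    p = config.true_params
    neck_share = 1.0 - config.head_share
    q_s = _euler_series(config.thorax_share * theta)
    neck_angles = neck_share * theta
    neck_angles[:, 0] += offset
    q_n = _euler_series(neck_angles)
    q_h = _euler_series(theta)

    o_s = np.zeros((len(time), 3))
    o_j1 = o_s + np.einsum("nij,j->ni", q_s, p.vs1)
    stick = p.l12 * q_n[:, :, 1]
    o_j2 = o_j1 + stick
    o_h = o_j2 + np.einsum("nij,j->ni", q_h, p.v2h)
    o_n = o_j1 + 0.5 * stick

    truth = TrialRecording(
        time=time,
        poses={
            "head": PoseSeries(o_h, q_h),
            "sternum": PoseSeries(o_s, q_s),
            "neck": PoseSeries(o_n, q_n),
        },
        sample_rate=config.sample_rate,
        meta={"task": task.label, "seed": config.seed},
    )

    ref = equilateral_reference_geometry(config.reference_side)
    mounting = config.mounting or {}
    markers = {}
    for body, (origin, q) in (("head", (o_h, q_h)), ("sternum", (o_s, q_s)),
                              ("neck", (o_n, q_n))):
        m = mounting.get(body, np.eye(3))
        lab_rot = q @ m
        pts = np.einsum("nij,kj->nki", lab_rot, ref) + origin[:, None, :]
        if config.marker_noise_sd > 0:
            pts = pts + rng.normal(0.0, config.marker_noise_sd, size=pts.shape)
        markers[body] = pts

    measured = TrialRecording(
        time=time, markers=markers, sample_rate=config.sample_rate,
        meta={"task": task.label, "seed": config.seed,
              "reference_geometry": ref,
              "calibration_window": (0.0, max(config.lead_in_s - dt, dt))},
    )
    measured = recover_poses(measured, ref)
    if config.orientation_noise_sd > 0:
        measured = add_orientation_noise(measured, config.orientation_noise_sd,
                                         seed=int(rng.integers(2**31)))
    return SimulatedTrial(recording=measured, truth=truth, params=p,
                          task=task, config=config)


def simulate_participant(tasks: Sequence[TaskSpec], config: SimulationConfig
                         ) -> list[SimulatedTrial]:
    """Simulate a task battery for one participant, one spawned seed per trial."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(tasks))
    return [
        simulate_trial(task, replace(config, seed=int(ss.generate_state(1)[0] % 2**31)))
        for task, ss in zip(tasks, seeds)
    ]


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def add_position_noise(recording: TrialRecording, sd: float,
                       seed: int | None = None) -> TrialRecording:
    """Add iid zero-mean Gaussian noise to every marker coordinate.

    Poses are copied unchanged — re-derive them with
    :func:`neckstick.recording.recover_poses` to propagate the noise through
    the rigid-body fit.  ``sd=0`` returns an identical copy.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    recording.require_bodies(what="markers")
    rng = np.random.default_rng(seed)
    markers = {}
    for body, pts in recording.markers.items():
        noisy = pts.copy()
        if sd > 0:
            noisy += rng.normal(0.0, sd, size=pts.shape)
        markers[body] = noisy
    poses = None
    if recording.poses is not None:
        poses = {b: PoseSeries(s.origins.copy(), s.rotations.copy())
                 for b, s in recording.poses.items()}
    return TrialRecording(time=recording.time.copy(), poses=poses, markers=markers,
                          sample_rate=recording.sample_rate, meta=dict(recording.meta))


def random_rotations(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """n random rotations: axis uniform on the sphere, angle |N(0, sd)|."""
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.abs(rng.normal(0.0, sd, size=n))
    return Rotation.from_rotvec(axes * angles[:, None]).as_matrix()


def add_orientation_noise(recording: TrialRecording, sd: float,
                          seed: int | None = None) -> TrialRecording:
    """Compose random small rotations onto every body's orientation series.

    Per body and sample the true orientation is left-composed with a random
    rotation whose axis is uniform on the sphere and whose angle is
    |N(0, sd)|-distributed.  ``sd=0`` returns an identical copy.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    recording.require_bodies(what="poses")
    rng = np.random.default_rng(seed)
    poses = {}
    for body, series in recording.poses.items():
        rot = series.rotations.copy()
        if sd > 0:
            noise = random_rotations(len(rot), sd, rng)
            rot = noise @ rot
        poses[body] = PoseSeries(series.origins.copy(), rot)
    markers = None
    if recording.markers is not None:
        markers = {b: m.copy() for b, m in recording.markers.items()}
    return TrialRecording(time=recording.time.copy(), poses=poses, markers=markers,
                          sample_rate=recording.sample_rate, meta=dict(recording.meta))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticParticipant:
    """Anthropometrics plus ground-truth model parameters of one simulated subject."""

    anthro: ParticipantAnthro
    params: NeckParameters
    thorax_share: float = 0.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3 * sd:
            return float(x)


def generate_cohort(n: int, seed: int | None = None,
                    beta0: float = 0.045, beta1: float = 1.2,
                    scatter_sd: float = 0.008,
                    thorax_share_range: tuple[float, float] = (0.0, 0.0)
                    ) -> list[SyntheticParticipant]:
    """Draw a synthetic cohort matching the reference-cohort statistics.

    Anthropometrics are Gaussian draws (truncated at +/-3 SD) with the means
    and SDs of the packaged eight-participant table; the true stick length
    follows the linear law ``l12 = beta1 * lC2C7 + beta0`` plus Gaussian
    scatter of ``scatter_sd`` meters (``scatter_sd=0`` puts every participant
    exactly on the line).  ``thorax_share_range`` optionally randomizes the
    movement-distribution knob across participants.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        c7s2 = _truncated_normal(rng, *COHORT_STATS["length_C7S2_cm"])
        c2c7 = _truncated_normal(rng, *COHORT_STATS["length_C2C7_cm"])
        anthro = ParticipantAnthro(
            id=f"S{i + 1:02d}",
            length_C7S2=c7s2,
            length_C2C7=min(c2c7, c7s2 - 1.0),
            height=_truncated_normal(rng, *COHORT_STATS["height_m"]),
            bmi=_truncated_normal(rng, *COHORT_STATS["bmi"]),
            age=_truncated_normal(rng, *COHORT_STATS["age_y"]),
        )
        l12 = beta1 * anthro.length_C2C7 * 1e-2 + beta0
        if scatter_sd > 0:
            l12 += rng.normal(0.0, scatter_sd)
        l12 = max(l12, 0.02)
        params = NeckParameters(
            l12=l12,
            vs1=np.asarray(DEFAULT_PARAMS.vs1) + rng.normal(0.0, 0.005, size=3),
            v2h=np.asarray(DEFAULT_PARAMS.v2h) + rng.normal(0.0, 0.005, size=3),
        )
        lo, hi = thorax_share_range
        share = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        out.append(SyntheticParticipant(anthro=anthro, params=params, thorax_share=share))
    return out
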