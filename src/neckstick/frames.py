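"""Coordinate-frame algebra for marker-based rigid-body kinematics.

A *pose* is an origin plus an orthonormal orientation.  Frames used throughout
the package: ``e`` (earth), ``l`` (lab, defined by the motion-capture volume),
``s`` (sternum), ``h`` (head) and ``n`` (neck).  The earth frame is taken to
coincide with the lab frame up to a fixed, configurable rotation (identity by
default): an optical system never observes magnetic north, so nothing is lost.

Axis convention: ``y`` is cranial (up at the upright calibration posture),
``z`` anterior, ``x`` lateral, right-handed.

Two origin conventions coexist in the motion-analysis literature and both
appear here, explicitly named:

* :func:`transform_point` implements the frame-change formula
  ``v_g = R @ v_b - o`` in which the origin enters *subtractively* after the
  rotation.  This is the convention of the model equations this package
  implements, and it is applied verbatim.
* Everywhere a pose is *constructed from data* (marker fits, simulation,
  trial files) ``Pose.origin`` holds the plain position of the body origin in
  the parent frame, which is also how origins enter the measured head
  position (``R_s^T (o_h - o_s)``).  The two conventions differ only by the
  sign of the origin; helpers are documented individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, FrameMismatchError, GimbalLockError

logger = logging.getLogger(__name__)

FRAME_LABELS = ("e", "l", "s", "h", "n")
BODY_LABELS = ("head", "sternum", "neck")

#: Default Euler sequence: flexion/extension (x), lateral inclination (z,
#: intermediate), axial rotation (y); intrinsic (body-fixed) axes.  Lateral
#: inclination is placed in the middle because its magnitude stays far from
#: 90 deg for any physiological neck motion, which keeps the decomposition
#: away from gimbal lock.
DEFAULT_EULER_SEQUENCE = "XZY"

_ORTHONORMALITY_TOL = 1e-9


def _check_rotation(rotation: np.ndarray, tol: float = _ORTHONORMALITY_TOL) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.linalg.norm(rotation.T @ rotation - np.eye(3))
    if err > tol:
        raise ValueError(f"rotation is not orthonormal (|R^T R - I| = {err:.3e})")
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > tol:
        raise ValueError(f"rotation determinant {det:.12f} is not +1")
    return rotation


@dataclass(frozen=True)
class Pose:
    """Origin plus orthonormal orientation relative to a named parent frame.

    ``origin`` is in meters, expressed in the parent frame identified by
    ``frame_label``.  ``body_label`` optionally names the frame being posed
    (e.g. ``"head"``) so that frame mismatches can be caught.
    """

    origin: np.ndarray
    rotation: np.ndarray
    frame_label: str = "l"
    body_label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))

    @classmethod
    def identity(cls, frame_label: str = "l", body_label: str | None = None) -> "Pose":
        return cls(np.zeros(3), np.eye(3), frame_label, body_label)

    def inverse(self) -> "Pose":
        """Inverse under the subtractive transform convention.

        If ``w = R v - o`` then ``v = R^T w + R^T o = R^T w - (-R^T o)``.
        """
        rt = self.rotation.T
        return Pose(-rt @ self.origin, rt, frame_label=self.body_label or self.frame_label,
                    body_label=self.frame_label)


@dataclass(frozen=True)
class MarkerTriplet:
    """Three marker positions (meters) in a common frame, rows = markers."""

    points: np.ndarray
    body_label: str = "head"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(3, 3)
        object.__setattr__(self, "points", pts)
        if triangle_area(pts) <= 1e-8:
            raise DegenerateGeometryError(
                f"markers of body '{self.body_label}' are collinear "
                f"(triangle area {triangle_area(pts):.3e} m^2)"
            )


def triangle_area(points: np.ndarray) -> float:
    """Area of the triangle spanned by three 3-D points."""
    p = np.asarray(points, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


def transform_point(v: np.ndarray, pose: Pose, v_frame: str | None = None) -> np.ndarray:
    """Change the frame of a position vector: ``R @ v - o``.

    The origin is subtracted after the rotation — the sign convention of the
    model equations, kept verbatim.  ``v_frame``, if given, must match the
    pose's ``body_label``.
    """
    if v_frame is not None and pose.body_label is not None and v_frame != pose.body_label:
        raise FrameMismatchError(
            f"vector is in frame '{v_frame}' but the pose maps frame '{pose.body_label}'"
        )
    return pose.rotation @ np.asarray(v, dtype=float).reshape(3) - pose.origin


def transform_direction(v: np.ndarray, pose: Pose) -> np.ndarray:
    """Change the frame of a *direction*: the origin is omitted, ``R @ v``."""
    return pose.rotation @ np.asarray(v, dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# Rigid-body pose from marker triplets (orthogonal Procrustes / Kabsch)
# ---------------------------------------------------------------------------

def kabsch(reference: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit rotation R and translation t with ``observed ~= R @ ref + t``.

    Least-squares over the marker correspondences; returns (R, t, rms) where
    rms is the root-mean-square residual distance in meters.
    """
    ref = np.asarray(reference, dtype=float)
    obs = np.asarray(observed, dtype=float)
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    h = ref_c.T @ obs_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = obs.mean(axis=0) - r @ ref.mean(axis=0)
    resid = obs - (ref @ r.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return r, t, rms


def pose_from_markers(markers: MarkerTriplet, reference_geometry: MarkerTriplet,
                      frame_label: str = "l") -> tuple[Pose, float]:
    """Rigid-body pose of a marker cluster relative to its reference geometry.

    Solves the orthogonal Procrustes problem (Kabsch): the returned pose
    minimizes the sum of squared distances between the rotated-and-translated
    reference geometry and the observed markers.  ``Pose.origin`` is the
    position of the cluster origin in the observation frame.  Returns
    ``(pose, rms_residual)``.
    """
    if markers.body_label != reference_geometry.body_label:
        raise FrameMismatchError(
            f"marker body '{markers.body_label}' does not match reference "
            f"body '{reference_geometry.body_label}'"
        )
    r, t, rms = kabsch(reference_geometry.points, markers.points)
    return Pose(t, r, frame_label=frame_label, body_label=markers.body_label), rms


def poses_from_marker_series(markers: np.ndarray, reference_geometry: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Kabsch over a time series.

    Parameters
    ----------
    markers : (n, k, 3) array of observed marker positions, meters.
    reference_geometry : (k, 3) array of the cluster's local geometry.

    Returns
    -------
    origins : (n, 3), rotations : (n, 3, 3), rms : (n,)
    """
    obs = np.asarray(markers, dtype=float)
    ref = np.asarray(reference_geometry, dtype=float)
    if triangle_area(ref[:3]) <= 1e-8:
        raise DegenerateGeometryError("reference geometry is collinear")
    ref_c = ref - ref.mean(axis=0)
    cen = obs.mean(axis=1, keepdims=True)
    obs_c = obs - cen
    h = np.einsum("ki,nkj->nij", ref_c, obs_c)
    u, _, vt = np.linalg.svd(h)
    v = np.swapaxes(vt, -1, -2)
    ut = np.swapaxes(u, -1, -2)
    d = np.sign(np.linalg.det(v @ ut))
    dmat = np.broadcast_to(np.eye(3), h.shape).copy()
    dmat[:, 2, 2] = d
    rot = v @ dmat @ ut
    origins = cen[:, 0, :] - np.einsum("nij,j->ni", rot, ref.mean(axis=0))
    fitted = np.einsum("nij,kj->nki", rot, ref) + origins[:, None, :]
    rms = np.sqrt(np.mean(np.sum((obs - fitted) ** 2, axis=2), axis=1))
    return origins, rot, rms


# ---------------------------------------------------------------------------
# Orientation averaging and calibration
# ---------------------------------------------------------------------------

def chordal_mean(rotations: np.ndarray) -> np.ndarray:
    """Chordal mean of a stack of rotations: sum, then project to SO(3).

    The projection is the orthogonal polar factor of the arithmetic mean,
    which is accurate for the small orientation spreads of a static
    calibration window.
    """
    rotations = np.asarray(rotations, dtype=float)
    if rotations.ndim == 2:
        rotations = rotations[None]
    m = rotations.mean(axis=0)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def rotation_angle(r: np.ndarray) -> float:
    """Rotation angle (radians) of a single rotation matrix."""
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def calibrate(recording, window: tuple[float, float],
              spread_threshold_deg: float = 2.0) -> dict[str, np.ndarray]:
    """Per-body calibration rotations from a static window of a recording.

    Averages each body's sensed orientation over ``window`` (chordal mean)
    and returns, per body, the transpose of that mean.  Composing a body's
    orientation series with its calibration rotation
    (:func:`apply_calibration`) makes the window-mean orientation identity,
    so an upright posture held during the window defines the reference
    ("zero") orientation of every body.  Relative orientations between bodies
    at any later time are unchanged up to these fixed rotations.
    """
    t0, t1 = window
    mask = (recording.time >= t0) & (recording.time <= t1)
    if not np.any(mask):
        raise ValueError(f"calibration window [{t0}, {t1}] s contains no samples")
    out: dict[str, np.ndarray] = {}
    for body, series in recording.poses.items():
        rots = series.rotations[mask]
        mean = chordal_mean(rots)
        spread = max(rotation_angle(mean.T @ r) for r in rots)
        if np.degrees(spread) > spread_threshold_deg:
            logger.warning(
                "calibration window orientation spread for body '%s' is %.2f deg "
                "(threshold %.2f deg); was the participant static?",
                body, np.degrees(spread), spread_threshold_deg,
            )
        out[body] = mean.T
    return out


def apply_calibration(recording, calibration: Mapping[str, np.ndarray],
                      lab_to_earth: np.ndarray | None = None):
    """Return a new recording with calibrated orientations.

    Each body's orientation series ``R(t)`` becomes ``R(t) @ C_b`` — the
    rotation of the body since the calibration posture, expressed in lab
    axes.  This is exact for arbitrary tripod mounting: the calibrated
    orientation of every body is the identity at the calibration posture and
    the physical rotation since then afterwards, all in one common frame.
    ``lab_to_earth`` optionally re-expresses that common frame in earth axes
    (conjugation by a fixed rotation, identity by default).
    """
    from .recording import PoseSeries, TrialRecording  # local import, no cycle at module load

    e = np.eye(3) if lab_to_earth is None else _check_rotation(lab_to_earth)
    poses = {}
    for body, series in recording.poses.items():
        c = _check_rotation(calibration[body])
        rot = np.einsum("ij,njk,kl->nil", e, series.rotations @ c, e.T)
        origins = series.origins @ e.T
        poses[body] = PoseSeries(origins=origins, rotations=rot)
    return TrialRecording(
        time=recording.time.copy(), poses=poses,
        markers=None if recording.markers is None else {b: m.copy() for b, m in recording.markers.items()},
        sample_rate=recording.sample_rate, meta=dict(recording.meta),
    )


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

def euler_from_rotation(rotation: np.ndarray,
                        sequence: str = DEFAULT_EULER_SEQUENCE) -> np.ndarray:
    """Euler angles (radians) of a rotation in the given sequence.

    The default intrinsic ``XZY`` sequence puts lateral inclination (z) in
    the intermediate slot, whose magnitude stays well below 90 deg for
    physiological neck motion, so gimbal lock is unreachable in practice.  An
    intermediate angle within 1e-6 rad of +/-90 deg raises
    :class:`GimbalLockError`.
    """
    rotation = _check_rotation(rotation, tol=1e-8)
    angles = Rotation.from_matrix(rotation).as_euler(sequence)
    if abs(abs(angles[1]) - np.pi / 2) < 1e-6:
        raise GimbalLockError(
            f"intermediate Euler angle is {np.degrees(angles[1]):.4f} deg; "
            f"sequence '{sequence}' is singular here"
        )
    return angles


def rotation_from_euler(angles: Sequence[float],
                        sequence: str = DEFAULT_EULER_SEQUENCE) -> np.ndarray:
    """Rotation matrix from Euler angles (radians) in the given sequence."""
    return Rotation.from_euler(sequence, np.asarray(angles, dtype=float)).as_matrix()
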