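"""The two-joint neck model.

The neck is modeled as a stiff stick of length ``l12`` between two ball
joints: J1 near vertebra C7 and J2 near vertebra C2.  J2 defines the head
center, so head position relative to the thorax is determined by just two
orientations — thorax and neck — plus ``l12``.  Rotation about the stick
axis is shared by both joints, leaving five degrees of freedom: the model
deliberately ignores translation along the spine, which is a few millimeters
at most.

The extended model used for identification adds two constant lever arms:
``vs1`` from the sternum-cluster origin to J1 (constant in the sternum
frame) and ``v2h`` from J2 to the forehead-cluster origin (constant in the
head frame).  The stick direction is the y-axis (cranial axis) of the neck
rigid body's calibrated orientation.

All orientations entering these functions are *calibrated*: identity at the
upright reference posture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FrameMismatchError
from .frames import Pose

_Y = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class NeckParameters:
    """The seven constants of the extended model.

    l12 : neck-stick length, meters (> 0).
    vs1 : sternum-origin -> J1 lever arm, meters, sternum frame.
    v2h : J2 -> head-origin lever arm, meters, head frame.
    """

    l12: float
    vs1: np.ndarray
    v2h: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vs1", np.asarray(self.vs1, dtype=float).reshape(3))
        object.__setattr__(self, "v2h", np.asarray(self.v2h, dtype=float).reshape(3))
        if not np.isfinite(self.l12) or self.l12 <= 0:
            raise ValueError(f"l12 must be a positive finite length, got {self.l12}")
        if not (np.all(np.isfinite(self.vs1)) and np.all(np.isfinite(self.v2h))):
            raise ValueError("vs1 and v2h must be finite")

    def as_vector(self) -> np.ndarray:
        """Parameter vector in the identification ordering (vs1, l12, v2h)."""
        return np.concatenate([self.vs1, [self.l12], self.v2h])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "NeckParameters":
        theta = np.asarray(theta, dtype=float).reshape(7)
        return cls(l12=float(theta[3]), vs1=theta[:3], v2h=theta[4:])


@dataclass(frozen=True)
class ProtractionResult:
    """Horizontal head displacement relative to the thorax.

    p_scalar : protraction magnitude ``l12 * sin(phi)``, meters (>= 0) —
        the norm of the stick component orthogonal to the thorax-up vector.
    p_vector : 3-D protraction vector ``v12 - l12 * u``, meters, where ``u``
        is the thorax-up (head-pointing) unit vector.
    phi : protraction angle between the stick and ``u``, radians.
    """

    p_scalar: float
    p_vector: np.ndarray
    phi: float


def _as_rotation(r) -> np.ndarray:
    if isinstance(r, Pose):
        return r.rotation
    return np.asarray(r, dtype=float).reshape(3, 3)


def neck_stick_vector(neck_orientation, l12: float) -> np.ndarray:
    """Stick vector from J1 to J2: ``l12`` times the neck body's y-axis.

    The y-axis is the second column of the (calibrated) neck orientation,
    i.e. the body-frame (0, 1, 0) mapped into the common frame.
    """
    r = _as_rotation(neck_orientation)
    return l12 * r[:, 1]


def up_vector(sternum_orientation, axis: str = "y") -> np.ndarray:
    """Thorax-fixed head-pointing unit vector, vertical at calibration.

    ``axis`` selects which column of the sternum orientation is "up":
    ``"y"`` (default, the cranial axis — the same axis the stick occupies at
    the upright posture, so protraction vanishes exactly at calibration),
    ``"z"``, or ``"earth"`` for a space-fixed vertical that does not rotate
    with the thorax.
    """
    if axis == "earth":
        return _Y.copy()
    r = _as_rotation(sternum_orientation)
    if axis == "y":
        return r[:, 1].copy()
    if axis == "z":
        return r[:, 2].copy()
    raise ValueError(f"unknown up-axis choice {axis!r}")


def predict_head_position(params: NeckParameters, neck_orientation,
                          sternum_orientation, head_orientation) -> np.ndarray:
    """Model-predicted forehead-cluster origin, in the sternum frame.

    The three-term chain: sternum origin -> J1 (``vs1``), J1 -> J2 (the
    stick, expressed in the sternum frame), J2 -> head origin (``v2h``
    rotated by the head-relative-to-sternum orientation)::

        o_hat = vs1 + l12 * (R_s^T R_n) @ (0,1,0) + (R_s^T R_h) @ v2h

    Orientations may be given as 3x3 matrices or :class:`Pose` objects (only
    the rotation of a pose is used).
    """
    rs = _as_rotation(sternum_orientation)
    rn = _as_rotation(neck_orientation)
    rh = _as_rotation(head_orientation)
    stick_s = rs.T @ neck_stick_vector(rn, params.l12)
    return params.vs1 + stick_s + (rs.T @ rh) @ params.v2h


def measured_head_position(head_pose: Pose, sternum_pose: Pose) -> np.ndarray:
    """Sternum-frame coordinates of the measured head-cluster origin.

    ``R_s^T (o_h - o_s)`` with both poses expressed in the same lab frame.
    """
    if head_pose.frame_label != sternum_pose.frame_label:
        raise FrameMismatchError(
            f"head pose is in frame '{head_pose.frame_label}' but sternum pose "
            f"in '{sternum_pose.frame_label}'"
        )
    return sternum_pose.rotation.T @ (head_pose.origin - sternum_pose.origin)


def protraction(neck_orientation, sternum_orientation, l12: float,
                up_axis: str = "y") -> ProtractionResult:
    """Protraction of the head (J2) relative to the thorax.

    The stick ``v12 = l12 * y_n`` is compared with the thorax-up direction
    ``u`` (see :func:`up_vector`).  The scalar protraction is the norm of the
    stick component orthogonal to ``u`` — exactly ``l12 * sin(phi)`` — and
    the protraction vector is ``v12 - l12 * u``.  The two agree in norm only
    as ``phi -> 0``; both are exposed, the scalar follows the
    orthogonal-component definition.
    """
    v12 = neck_stick_vector(neck_orientation, l12)
    u = up_vector(sternum_orientation, axis=up_axis)
    p_vec = v12 - l12 * u
    along = float(v12 @ u)
    perp = v12 - along * u
    p_scalar = float(np.linalg.norm(perp))
    phi = float(np.arctan2(p_scalar, along))
    return ProtractionResult(p_scalar=p_scalar, p_vector=p_vec, phi=phi)


def protraction_series(recording, l12: float, up_axis: str = "y"):
    """Per-sample protraction table for a calibrated recording.

    Returns a :class:`pandas.DataFrame` with columns ``time_s``, ``p_mm``,
    ``phi_deg``, ``px_mm``, ``py_mm``, ``pz_mm`` (reporting units:
    millimeters and degrees).
    """
    import pandas as pd

    recording.require_bodies(("neck", "sternum"))
    rn = recording.poses["neck"].rotations
    rs = recording.poses["sternum"].rotations
    v12 = l12 * rn[:, :, 1]
    if up_axis == "earth":
        u = np.broadcast_to(_Y, v12.shape)
    else:
        col = {"y": 1, "z": 2}[up_axis]
        u = rs[:, :, col]
    along = np.sum(v12 * u, axis=1)
    perp = v12 - along[:, None] * u
    p = np.linalg.norm(perp, axis=1)
    phi = np.arctan2(p, along)
    p_vec = v12 - l12 * u
    return pd.DataFrame({
        "time_s": recording.time,
        "p_mm": p * 1e3,
        "phi_deg": np.degrees(phi),
        "px_mm": p_vec[:, 0] * 1e3,
        "py_mm": p_vec[:, 1] * 1e3,
        "pz_mm": p_vec[:, 2] * 1e3,
    })
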