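"""Containers for synchronized rigid-body trajectories.

A trial holds time-stamped marker positions and/or derived pose series for
the three tracked bodies (head, sternum, neck), sampled at a fixed rate
(120 Hz by default).  All positions are meters, all rotations 3x3 matrices
mapping body axes into the common (lab or calibrated) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NeckstickError

BODIES = ("head", "sternum", "neck")


@dataclass
class PoseSeries:
    """Origin and orientation time series of one rigid body."""

    origins: np.ndarray    # (n, 3) meters
    rotations: np.ndarray  # (n, 3, 3)

    def __post_init__(self):
        self.origins = np.asarray(self.origins, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.origins.ndim != 2 or self.origins.shape[1] != 3:
            raise ValueError(f"origins must be (n, 3), got {self.origins.shape}")
        if self.rotations.shape != (len(self.origins), 3, 3):
            raise ValueError(
                f"rotations must be (n, 3, 3) matching origins, got {self.rotations.shape}"
            )

    def __len__(self) -> int:
        return len(self.origins)


@dataclass
class TrialRecording:
    """Synchronized head/sternum/neck trajectories of one trial.

    ``markers`` maps body label to an (n, 3, 3) array (sample, marker,
    coordinate); ``poses`` maps body label to a :class:`PoseSeries`.  Either
    may be absent (``None`` / missing key) depending on the processing stage:
    files carry markers, the model works on poses.
    """

    time: np.ndarray
    poses: dict[str, PoseSeries] | None = None
    markers: dict[str, np.ndarray] | None = None
    sample_rate: float = 120.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        if np.any(np.diff(self.time) <= 0):
            raise NeckstickError("trial time stamps must be strictly increasing")
        for name, group in (("poses", self.poses), ("markers", self.markers)):
            if group is None:
                continue
            for body, data in group.items():
                if len(data) != len(self.time):
                    raise NeckstickError(
                        f"{name}['{body}'] has {len(data)} samples, time has {len(self.time)}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def require_bodies(self, bodies=BODIES, what: str = "poses") -> None:
        group = getattr(self, what)
        missing = [b for b in bodies if group is None or b not in group]
        if missing:
            raise NeckstickError(f"recording is missing {what} for bodies: {missing}")


def recover_poses(recording: TrialRecording, reference_geometry) -> TrialRecording:
    """Compute per-sample rigid-body poses from the recording's markers.

    ``reference_geometry`` maps body label to a (3, 3) local marker geometry
    (or a single (3, 3) array shared by all bodies).  Uses the vectorized
    orthogonal-Procrustes fit; the per-sample rms marker residual is stored
    in ``meta['pose_rms']``.
    """
    from .frames import poses_from_marker_series

    recording.require_bodies(what="markers")
    if isinstance(reference_geometry, np.ndarray):
        reference_geometry = {b: reference_geometry for b in recording.markers}
    poses = {}
    rms_all = {}
    for body, series in recording.markers.items():
        origins, rotations, rms = poses_from_marker_series(series, reference_geometry[body])
        poses[body] = PoseSeries(origins=origins, rotations=rotations)
        rms_all[body] = rms
    meta = dict(recording.meta)
    meta["pose_rms"] = rms_all
    return TrialRecording(time=recording.time.copy(), poses=poses,
                          markers={b: m.copy() for b, m in recording.markers.items()},
                          sample_rate=recording.sample_rate, meta=meta)
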