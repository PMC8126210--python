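"""Linear least-squares identification of the seven model parameters.

For every sample the predicted head position is linear in the unknowns
``theta = (vs1, l12, v2h)``::

    o_hat(t) = [ I3 | y_n^s(t) | R_h^s(t) ] @ theta

where ``y_n^s`` is the neck body's y-axis expressed in the sternum frame and
``R_h^s`` the head-relative-to-sternum orientation.  Stacking all samples of
all trials of one participant against the measured head positions gives one
overdetermined linear system solved in a single step by a rank-revealing
orthogonal decomposition (SVD).  Identifiability requires rank 7, i.e. at
least two distinct neck orientations and two distinct head-relative
orientations somewhere in the pooled trials; purely static data are rejected
with the deficient parameter directions named.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import IdentifiabilityError, NeckstickError
from .model import NeckParameters
from .recording import TrialRecording

#: Parameter names in the design-matrix column ordering.
PARAM_NAMES = ("vs1_x", "vs1_y", "vs1_z", "l12", "v2h_x", "v2h_y", "v2h_z")

#: Relative singular-value cutoff for the numerical rank decision.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ResidualSummary:
    """Per-axis signed-error summary in millimeters: mean, 5% and 95% percentiles."""

    mean_error: float
    p5: float
    p95: float

    def __post_init__(self):
        if self.p5 > self.p95:
            raise ValueError("p5 must not exceed p95")


@dataclass(frozen=True)
class FitResult:
    """Least-squares solution with pooled per-axis residual summaries."""

    params: NeckParameters
    per_axis_residuals: dict[str, ResidualSummary]
    n_samples: int
    condition_number: float
    singular_values: np.ndarray


def build_design_matrix(recording: TrialRecording) -> tuple[np.ndarray, np.ndarray]:
    """Stacked linear system (A, b) of one calibrated recording.

    ``A`` is (3n, 7): one 3x7 block ``[I3 | y_n^s | R_h^s]`` per sample;
    ``b`` is (3n,): the measured head position in the sternum frame,
    ``R_s^T (o_h - o_s)``.  Unknown ordering is ``(vs1, l12, v2h)``.
    """
    recording.require_bodies()
    rs = recording.poses["sternum"].rotations
    rn = recording.poses["neck"].rotations
    rh = recording.poses["head"].rotations
    rst = np.swapaxes(rs, -1, -2)
    y_ns = np.einsum("nij,nj->ni", rst, rn[:, :, 1])
    rhs = rst @ rh
    n = recording.n_samples
    blocks = np.zeros((n, 3, 7))
    blocks[:, :, :3] = np.eye(3)
    blocks[:, :, 3] = y_ns
    blocks[:, :, 4:] = rhs
    delta = recording.poses["head"].origins - recording.poses["sternum"].origins
    obs = np.einsum("nij,nj->ni", rst, delta)
    return blocks.reshape(3 * n, 7), obs.reshape(3 * n)


def solve_least_squares(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based minimum-norm least squares with a rank check.

    Raises :class:`IdentifiabilityError` naming the deficient parameter
    directions when the numerical rank (relative cutoff ``RANK_RTOL``) is
    below 7.  Returns ``(theta, singular_values)``.
    """
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    tol = s[0] * RANK_RTOL if s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < 7:
        deficient = []
        for row in vt[rank:]:
            i = int(np.argmax(np.abs(row)))
            deficient.append(PARAM_NAMES[i])
        raise IdentifiabilityError(
            f"pooled system has numerical rank {rank} < 7; motion does not excite: "
            f"{sorted(set(deficient))}. Add trials with distinct neck and head "
            f"orientations (static-only data cannot identify the model).",
            deficient_directions=deficient,
        )
    theta = vt.T @ ((u.T @ b) / s)
    return theta, s


def residual_stats(predicted: np.ndarray, measured: np.ndarray) -> dict[str, ResidualSummary]:
    """Per-axis signed-error summaries (predicted minus measured), millimeters.

    Mean error plus 5% and 95% percentiles (linear interpolation between
    order statistics).  Negative mean errors therefore indicate
    under-prediction along that axis.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise NeckstickError(
            f"predicted {predicted.shape} and measured {measured.shape} differ in shape"
        )
    if predicted.size == 0:
        raise NeckstickError("cannot summarize an empty series")
    err_mm = (predicted - measured) * 1e3
    out = {}
    for i, axis in enumerate("xyz"):
        e = err_mm[:, i]
        p5, p95 = np.percentile(e, [5.0, 95.0])
        out[axis] = ResidualSummary(mean_error=float(e.mean()), p5=float(p5), p95=float(p95))
    return out


def fit_parameters(recordings: Sequence[TrialRecording] | TrialRecording) -> FitResult:
    """Identify ``(vs1, l12, v2h)`` from the pooled trials of one participant.

    All trials are stacked into a single linear system (the model's
    double-sum over trials and sample instants) and solved by SVD.  Residual
    summaries are computed per axis over all pooled samples.
    """
    if isinstance(recordings, TrialRecording):
        recordings = [recordings]
    if not recordings:
        raise NeckstickError("no recordings to fit")
    systems = [build_design_matrix(r) for r in recordings]
    a = np.vstack([s[0] for s in systems])
    b = np.concatenate([s[1] for s in systems])
    if a.shape[0] < 9:
        raise NeckstickError(
            f"need at least 3 samples (9 scalar equations) for 7 unknowns, got {a.shape[0] // 3}"
        )
    theta, s = solve_least_squares(a, b)
    params = NeckParameters.from_vector(theta)
    predicted = (a @ theta).reshape(-1, 3)
    summaries = residual_stats(predicted, b.reshape(-1, 3))
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    return FitResult(params=params, per_axis_residuals=summaries,
                     n_samples=a.shape[0] // 3, condition_number=cond,
                     singular_values=s)


def predicted_positions(recording: TrialRecording, params: NeckParameters) -> np.ndarray:
    """Model-predicted head positions (n, 3) for a calibrated recording."""
    a, _ = build_design_matrix(recording)
    return (a @ params.as_vector()).reshape(-1, 3)


def measured_positions(recording: TrialRecording) -> np.ndarray:
    """Measured sternum-frame head positions (n, 3) of a recording."""
    _, b = build_design_matrix(recording)
    return b.reshape(-1, 3)


def per_trial_residuals(recordings: Sequence[TrialRecording],
                        params: NeckParameters) -> list[dict[str, ResidualSummary]]:
    """Per-axis residual summaries of each trial under one fixed fit."""
    out = []
    for rec in recordings:
        a, b = build_design_matrix(rec)
        predicted = (a @ params.as_vector()).reshape(-1, 3)
        out.append(residual_stats(predicted, b.reshape(-1, 3)))
    return out


def j2_positions(recording: TrialRecording, params: NeckParameters) -> np.ndarray:
    """Predicted J2 (head-center) trajectory (n, 3) in the sternum frame.

    ``vs1 + l12 * y_n^s(t)`` — linear in ``l12``: perturbing the length by
    ``delta`` moves J2 by exactly ``delta`` along the instantaneous stick
    direction.
    """
    recording.require_bodies(("neck", "sternum"))
    rs = recording.poses["sternum"].rotations
    rn = recording.poses["neck"].rotations
    y_ns = np.einsum("nij,nj->ni", np.swapaxes(rs, -1, -2), rn[:, :, 1])
    return params.vs1 + params.l12 * y_ns
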