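"""Anthropometric neck-length prediction.

The effective neck-stick length ``l12`` of the two-joint model cannot be
palpated — the joints are not anatomical landmarks — but the distance
between vertebrae C2 and C7 can.  A linear predictor

    l12 = beta1 * lC2C7 + beta0

is fitted across participants from their individually identified stick
lengths.  A packaged reference cohort of eight healthy adults (palpated
C7–S2 and C2–C7 lengths, height, BMI, age) ships with the package and is
also the statistical template for the synthetic cohort generator.

Internally everything is meters; palpated lengths are centimeters at the
file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NeckstickError
from .identify import FitResult, ResidualSummary, j2_positions, residual_stats
from .model import NeckParameters

ANTHRO_COLUMNS = ("id", "length_C7S2_cm", "length_C2C7_cm", "height_m", "bmi", "age_y")


@dataclass(frozen=True)
class ParticipantAnthro:
    """One participant's descriptive characteristics (lengths in cm)."""

    id: str
    length_C7S2: float
    length_C2C7: float
    height: float
    bmi: float
    age: float

    def __post_init__(self):
        if self.length_C2C7 <= 0 or self.length_C7S2 <= 0:
            raise ValueError("palpated lengths must be positive")
        if self.length_C2C7 >= self.length_C7S2:
            raise ValueError("C2-C7 length must be shorter than C7-S2 length")


@dataclass(frozen=True)
class LengthModel:
    """Linear neck-length predictor: ``l12 = beta1 * lC2C7 + beta0`` (meters)."""

    beta0: float
    beta1: float
    residual_sd: float

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


def load_reference_cohort() -> list[ParticipantAnthro]:
    """The packaged eight-participant reference cohort."""
    with resources.files("neckstick.data").joinpath("reference_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    return cohort_from_frame(df)


def cohort_from_frame(df: pd.DataFrame) -> list[ParticipantAnthro]:
    missing = [c for c in ANTHRO_COLUMNS if c not in df.columns]
    if missing:
        raise NeckstickError(f"anthropometrics table is missing columns: {missing}")
    return [
        ParticipantAnthro(
            id=str(row["id"]),
            length_C7S2=float(row["length_C7S2_cm"]),
            length_C2C7=float(row["length_C2C7_cm"]),
            height=float(row["height_m"]),
            bmi=float(row["bmi"]),
            age=float(row["age_y"]),
        )
        for _, row in df.iterrows()
    ]


def cohort_to_frame(cohort: Sequence[ParticipantAnthro]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "length_C7S2_cm": [p.length_C7S2 for p in cohort],
            "length_C2C7_cm": [p.length_C2C7 for p in cohort],
            "height_m": [p.height for p in cohort],
            "bmi": [p.bmi for p in cohort],
            "age_y": [p.age for p in cohort],
        }
    )


def cohort_descriptives(cohort: Sequence[ParticipantAnthro]) -> pd.DataFrame:
    """Mean and sample standard deviation (n-1) of each numeric column.

    With a single participant the SD is undefined and reported as NaN.
    """
    if not cohort:
        raise NeckstickError("cohort is empty")
    df = cohort_to_frame(cohort).drop(columns="id")
    mean = df.mean()
    sd = df.std(ddof=1) if len(df) > 1 else pd.Series(np.nan, index=df.columns)
    return pd.DataFrame({"mean": mean, "sd": sd})


def fit_length_model(l_c2c7: np.ndarray, l12: np.ndarray) -> LengthModel:
    """Ordinary least squares of identified stick lengths on palpated C2-C7.

    Both arguments are meters.  ``residual_sd`` is the regression standard
    error, ``sqrt(SS_res / (n - 2))`` (0 when n == 2 or the points are
    exactly collinear).
    """
    x = np.asarray(l_c2c7, dtype=float).reshape(-1)
    y = np.asarray(l12, dtype=float).reshape(-1)
    if x.shape != y.shape or x.size < 2:
        raise NeckstickError("need at least two (lC2C7, l12) pairs of equal length")
    if np.ptp(x) < 1e-12:
        raise NeckstickError("all lC2C7 values are equal; the predictor is degenerate")
    a = np.column_stack([x, np.ones_like(x)])
    (beta1, beta0), *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - (beta1 * x + beta0)
    dof = x.size - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return LengthModel(beta0=float(beta0), beta1=float(beta1), residual_sd=residual_sd)


def predict_l12(model: LengthModel, l_c2c7: float) -> float:
    """Predicted stick length (meters) for a palpated C2-C7 length (meters)."""
    if l_c2c7 <= 0:
        raise ValueError("lC2C7 must be positive")
    pred = model.beta1 * l_c2c7 + model.beta0
    if pred <= 0:
        raise NeckstickError(
            f"predicted neck length {pred * 1e3:.1f} mm is non-physical "
            f"(lC2C7 = {l_c2c7 * 1e3:.1f} mm)"
        )
    return float(pred)


def evaluate_parametrized_model(recordings, predicted_l12: float,
                                reference_fit: FitResult) -> dict[str, ResidualSummary]:
    """Residuals of the anthropometrically parametrized model against the fitted one.

    Recomputes the J2 (head-center) trajectory with ``l12`` replaced by the
    prediction — the lever arm ``vs1`` unchanged — and summarizes per-axis
    differences against the J2 trajectory under the participant's own fitted
    length, pooled over the given calibrated recordings.  Because J2 is
    linear in ``l12``, the per-sample difference is exactly
    ``(predicted_l12 - fitted_l12)`` along the instantaneous stick direction.
    """
    if reference_fit is None:
        raise NeckstickError("a reference fit for the same participant is required")
    from .recording import TrialRecording

    if isinstance(recordings, TrialRecording):
        recordings = [recordings]
    ref = reference_fit.params
    param = NeckParameters(l12=predicted_l12, vs1=ref.vs1, v2h=ref.v2h)
    ref_traj = np.vstack([j2_positions(r, ref) for r in recordings])
    par_traj = np.vstack([j2_positions(r, param) for r in recordings])
    return residual_stats(par_traj, ref_traj)
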