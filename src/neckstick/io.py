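"""Plain-text file formats and run configuration.

Trial trajectories travel as comma-separated tables with a header row:
``time_s`` followed by ``<body>_<marker>_<axis>_mm`` columns for bodies
``head``, ``sternum``, ``neck``, markers 1..3 and axes x/y/z, positions in
millimeters, sampled at 120 Hz by default.  Every numeric output file
declares its units in the header row; reported quantities are millimeters
and degrees, rounded to two decimals, while the in-memory API is meters and
radians throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anthropometry import LengthModel, cohort_from_frame, cohort_to_frame
from .errors import TrialParseError
from .identify import FitResult, ResidualSummary
from .model import NeckParameters
from .recording import BODIES, TrialRecording

_AXES = ("x", "y", "z")


def _marker_columns() -> list[str]:
    return [f"{body}_{k}_{ax}_mm" for body in BODIES for k in (1, 2, 3) for ax in _AXES]


def write_trial(path, recording: TrialRecording) -> None:
    """Write a recording's marker trajectories as a trial CSV (mm)."""
    recording.require_bodies(what="markers")
    data = {"time_s": recording.time}
    for body in BODIES:
        pts = recording.markers[body]
        for k in range(3):
            for a, ax in enumerate(_AXES):
                data[f"{body}_{k + 1}_{ax}_mm"] = pts[:, k, a] * 1e3
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_trial(path, sample_rate: float = 120.0) -> TrialRecording:
    """Read a trial CSV into a recording (markers in meters).

    Validates the header, rejects NaN cells (naming column and line) and
    non-monotone time stamps.  Pose series are not derived here; use
    :func:`neckstick.recording.recover_poses` with the cluster geometry.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise TrialParseError(f"{path}: cannot parse trial file ({exc})") from exc
    expected = ["time_s"] + _marker_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    bad = df[expected].isna()
    if bad.to_numpy().any():
        col = bad.any().idxmax()
        line = int(bad[bad.any(axis=1)].index[0]) + 2  # +1 header, +1 one-based
        raise TrialParseError(f"{path}: NaN value in column '{col}' at line {line}")
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        i = int(np.argmax(np.diff(time) <= 0))
        raise TrialParseError(f"{path}: time not strictly increasing at line {i + 3}")
    markers = {}
    for body in BODIES:
        cols = [f"{body}_{k}_{ax}_mm" for k in (1, 2, 3) for ax in _AXES]
        markers[body] = df[cols].to_numpy(dtype=float).reshape(-1, 3, 3) * 1e-3
    return TrialRecording(time=time, markers=markers, sample_rate=sample_rate,
                          meta={"source": str(path)})


def params_to_dict(params: NeckParameters) -> dict:
    return {
        "l12_mm": params.l12 * 1e3,
        "vs1_mm": (params.vs1 * 1e3).tolist(),
        "v2h_mm": (params.v2h * 1e3).tolist(),
    }


def write_params(path, params: NeckParameters, extra: dict | None = None) -> None:
    payload = params_to_dict(params)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path) -> NeckParameters:
    d = json.loads(Path(path).read_text())
    return NeckParameters(l12=d["l12_mm"] * 1e-3,
                          vs1=np.asarray(d["vs1_mm"]) * 1e-3,
                          v2h=np.asarray(d["v2h_mm"]) * 1e-3)


def residual_table(rows: dict[str, dict[str, ResidualSummary]]) -> pd.DataFrame:
    """Wide residual table: one row per participant, ME/p5/p95 per axis (mm)."""
    data = []
    for pid, summaries in rows.items():
        row = {"participant": pid}
        for axis in ("x", "y", "z"):
            s = summaries[axis]
            row[f"ME_{axis}_mm"] = round(s.mean_error, 2)
            row[f"p5_{axis}_mm"] = round(s.p5, 2)
            row[f"p95_{axis}_mm"] = round(s.p95, 2)
        data.append(row)
    return pd.DataFrame(data)


def write_length_model(path, model: LengthModel, extra: dict | None = None) -> None:
    payload = {"beta0_mm": model.beta0 * 1e3, "beta1": model.beta1,
               "residual_sd_mm": model.residual_sd * 1e3}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_anthropometrics(path):
    """Read an anthropometrics CSV (id, lengths in cm, height in m, bmi, age)."""
    return cohort_from_frame(pd.read_csv(path))


def write_anthropometrics(path, cohort) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    Every seed, noise level and tolerance here is echoed into the emitted
    run log so results are reproducible from the log alone.
    """

    out_dir: str = "neckstick_run"
    n_subjects: int = 8
    seed: int = 0
    sample_rate: float = 120.0
    marker_noise_sd_mm: float = 0.1
    free_duration_s: float = 30.0
    pattern_duration_s: float = 12.0
    calibration_spread_deg: float = 2.0
    thorax_share_range: tuple[float, float] = (0.0, 0.0)
    length_scatter_sd_mm: float = 8.0
    run_noise_sweep: bool = False
    noise_multipliers: tuple[float, ...] = (1.0, 5.0, 10.0)
    noise_repetitions: int = 25
    base_orientation_sd_deg: float = 0.1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise TrialParseError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("thorax_share_range", "noise_multipliers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
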