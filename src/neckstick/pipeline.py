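"""End-to-end synthetic study pipeline.

Mirrors the full analysis workflow on a generated cohort: simulate each
participant's task battery, calibrate from the static lead-in, identify the
seven model parameters per participant by pooled least squares, regress the
identified stick lengths on the palpated C2-C7 lengths across participants,
re-evaluate each participant's head-center trajectory under the
anthropometric length prediction, and optionally run the measurement-noise
sweep.  Emits parameter JSONs, per-participant residual CSV tables for both
the fitted and the parametrized model, the length-model JSON, and a run log
with package versions, configuration, and every seed used.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anthropometry import (LengthModel, cohort_to_frame, evaluate_parametrized_model,
                            fit_length_model, predict_l12)
from .errors import NeckstickError
from .frames import apply_calibration, calibrate
from .identify import FitResult, fit_parameters
from .io import RunConfig, residual_table, write_length_model, write_params
from .noise import run_noise_sweep, summarize_sweep, sweep_to_long_frame
from .synthetic import (SimulationConfig, SyntheticParticipant, TaskSpec,
                        generate_cohort, simulate_participant, standard_task_set)

logger = logging.getLogger(__name__)


@dataclass
class ParticipantResult:
    participant: SyntheticParticipant
    fit: FitResult
    per_axis_residuals: dict
    parametrized_residuals: dict | None = None
    predicted_l12: float | None = None


@dataclass
class PipelineReport:
    participants: list[ParticipantResult]
    length_model: LengthModel
    fitted_table: pd.DataFrame
    parametrized_table: pd.DataFrame
    sweep_summary: pd.DataFrame | None
    out_dir: Path


def _tasks(config: RunConfig) -> list[TaskSpec]:
    tasks = standard_task_set(free_duration_s=config.free_duration_s)
    return [
        t if t.pattern in ("free", "static")
        else TaskSpec(t.pattern, t.head_position_mode, duration_s=config.pattern_duration_s)
        for t in tasks
    ]


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full synthetic study; returns the report bundle.

    Any stage failure aborts with a stage-labeled error.  Re-running with
    the same configuration and seed reproduces every output byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    cohort_seed, sim_seed, sweep_seed = (int(s.generate_state(1)[0] % 2**31)
                                         for s in master.spawn(3))
    log: dict = {
        "package": "neckstick", "version": __version__,
        "python": platform.python_version(), "numpy": np.__version__,
        "config": config.to_dict(),
        "seeds": {"master": config.seed, "cohort": cohort_seed,
                  "simulation": sim_seed, "noise_sweep": sweep_seed},
        "stages": [],
    }

    def stage(name):
        log["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("generate_cohort")
        cohort = generate_cohort(config.n_subjects, seed=cohort_seed,
                                 scatter_sd=config.length_scatter_sd_mm * 1e-3,
                                 thorax_share_range=config.thorax_share_range)
        cohort_to_frame([p.anthro for p in cohort]).to_csv(out / "cohort.csv", index=False)
    except NeckstickError as exc:
        raise NeckstickError(f"stage generate_cohort failed: {exc}") from exc

    tasks = _tasks(config)
    sim_seeds = np.random.SeedSequence(sim_seed).spawn(len(cohort))
    results: list[ParticipantResult] = []
    all_trials: dict[str, list] = {}
    for participant, ss in zip(cohort, sim_seeds):
        pid = participant.anthro.id
        try:
            stage(f"simulate+fit:{pid}")
            sim_cfg = SimulationConfig(
                true_params=participant.params, anthro=participant.anthro,
                sample_rate=config.sample_rate,
                marker_noise_sd=config.marker_noise_sd_mm * 1e-3,
                seed=int(ss.generate_state(1)[0] % 2**31),
                thorax_share=participant.thorax_share,
            )
            trials = simulate_participant(tasks, sim_cfg)
            calibrated = [
                apply_calibration(
                    t.recording,
                    calibrate(t.recording, t.recording.meta["calibration_window"],
                              spread_threshold_deg=config.calibration_spread_deg))
                for t in trials
            ]
            fit = fit_parameters(calibrated)
            results.append(ParticipantResult(
                participant=participant, fit=fit,
                per_axis_residuals=fit.per_axis_residuals))
            all_trials[pid] = (trials, calibrated)
            write_params(out / f"params_{pid}.json", fit.params,
                         extra={"participant": pid,
                                "true_l12_mm": participant.params.l12 * 1e3,
                                "n_samples": fit.n_samples})
        except NeckstickError as exc:
            raise NeckstickError(f"stage fit:{pid} failed: {exc}") from exc

    try:
        stage("length_model")
        x = np.array([r.participant.anthro.length_C2C7 * 1e-2 for r in results])
        y = np.array([r.fit.params.l12 for r in results])
        length_model = fit_length_model(x, y)
        write_length_model(out / "length_model.json", length_model,
                           extra={"n_participants": len(results)})
    except NeckstickError as exc:
        raise NeckstickError(f"stage length_model failed: {exc}") from exc

    try:
        stage("parametrized_validation")
        for r in results:
            pred = predict_l12(length_model, r.participant.anthro.length_C2C7 * 1e-2)
            r.predicted_l12 = pred
            _, calibrated = all_trials[r.participant.anthro.id]
            r.parametrized_residuals = evaluate_parametrized_model(calibrated, pred, r.fit)
    except NeckstickError as exc:
        raise NeckstickError(f"stage parametrized_validation failed: {exc}") from exc

    fitted_table = residual_table(
        {r.participant.anthro.id: r.per_axis_residuals for r in results})
    parametrized_table = residual_table(
        {r.participant.anthro.id: r.parametrized_residuals for r in results})
    fitted_table.to_csv(out / "residuals_fitted_mm.csv", index=False)
    parametrized_table.to_csv(out / "residuals_parametrized_mm.csv", index=False)

    sweep_summary = None
    if config.run_noise_sweep:
        try:
            stage("noise_sweep")
            pid = results[0].participant.anthro.id
            trials, _ = all_trials[pid]
            clean_cfg = trials[0].config
            if clean_cfg.marker_noise_sd > 0:
                from dataclasses import replace
                clean = simulate_participant(tasks, replace(clean_cfg, marker_noise_sd=0.0))
            else:
                clean = trials
            sweep = run_noise_sweep(
                clean, base_orientation_sd=np.radians(config.base_orientation_sd_deg),
                multipliers=config.noise_multipliers,
                repetitions=config.noise_repetitions, seed=sweep_seed,
                reference_l12=results[0].fit.params.l12)
            sweep_summary = summarize_sweep(sweep)
            sweep_summary.round(4).to_csv(out / "noise_sweep_summary.csv", index=False)
            sweep_to_long_frame(sweep).round(4).to_csv(out / "noise_sweep_long.csv",
                                                       index=False)
        except NeckstickError as exc:
            raise NeckstickError(f"stage noise_sweep failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return PipelineReport(participants=results, length_model=length_model,
                          fitted_table=fitted_table,
                          parametrized_table=parametrized_table,
                          sweep_summary=sweep_summary, out_dir=out)
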