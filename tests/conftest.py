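"""Shared fixtures: small simulated trials and calibrated recordings."""

import numpy as np
import pytest

from neckstick import (SimulationConfig, TaskSpec, apply_calibration, calibrate,
                       simulate_participant, simulate_trial)


def calibrated(trial):
    rec = trial.recording
    cal = calibrate(rec, rec.meta["calibration_window"])
    return apply_calibration(rec, cal)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(marker_noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_config):
    return simulate_trial(TaskSpec("zigzag", duration_s=6.0), noiseless_config)


@pytest.fixture(scope="session")
def short_battery(noiseless_config):
    """Noise-free standard-style battery of one subject, shortened patterns."""
    tasks = [
        TaskSpec("static", duration_s=2.0),
        TaskSpec("zigzag", "neutral", duration_s=6.0),
        TaskSpec("zigzag", "protracted", duration_s=6.0),
        TaskSpec("cross", "neutral", duration_s=6.0),
        TaskSpec("cross", "protracted", duration_s=6.0),
        TaskSpec("free", duration_s=8.0),
    ]
    return simulate_participant(tasks, noiseless_config)


@pytest.fixture(scope="session")
def calibrated_battery(short_battery):
    return [calibrated(t) for t in short_battery]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
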