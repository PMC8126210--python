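"""Simulate one participant's task battery and identify the neck model.

Generates marker trajectories for the standard task set (static sitting,
zigzag/cross patterns in neutral and protracted head position, free
movement) from known two-joint parameters with 0.1 mm marker noise, then
recovers poses, calibrates on the static lead-in of each trial, and fits the
seven parameters by pooled linear least squares.
"""

import numpy as np

from neckstick import (SimulationConfig, apply_calibration, calibrate,
                       fit_parameters, simulate_participant, standard_task_set)

config = SimulationConfig(seed=42, marker_noise_sd=0.1e-3)
trials = simulate_participant(standard_task_set(free_duration_s=15.0), config)

calibrated = [
    apply_calibration(t.recording,
                      calibrate(t.recording, t.recording.meta["calibration_window"]))
    for t in trials
]
fit = fit_parameters(calibrated)

true = config.true_params
print(f"true neck-stick length : {true.l12 * 1e3:7.2f} mm")
print(f"fitted                  : {fit.params.l12 * 1e3:7.2f} mm")
print(f"thorax lever arm error  : {np.abs(fit.params.vs1 - true.vs1).max() * 1e3:7.4f} mm")
print(f"head lever arm error    : {np.abs(fit.params.v2h - true.v2h).max() * 1e3:7.4f} mm")
print(f"condition number        : {fit.condition_number:7.1f}")
for axis, s in fit.per_axis_residuals.items():
    print(f"residual {axis}: ME {s.mean_error:+8.4f} mm   5%/95%: "
          f"{s.p5:+8.4f} / {s.p95:+8.4f} mm")
# The fitted length should sit within a fraction of a millimeter of the
# truth at this noise level; the residual percentiles show the sub-millimeter
# spread left by marker noise after the model has absorbed the motion.
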