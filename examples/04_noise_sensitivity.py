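"""Monte-Carlo sensitivity of the stick-length estimate to measurement noise.

Injects position and orientation noise at 1x, 5x and 10x a base level
(0.1 mm / 0.1 deg) into clean simulated trials, re-runs the full
identification pipeline 25 times per level with common random numbers, and
summarizes the estimator's distribution.
"""

from neckstick import (SimulationConfig, TaskSpec, run_noise_sweep,
                       simulate_participant, standard_task_set, summarize_sweep)

tasks = [t if t.pattern in ("free", "static")
         else TaskSpec(t.pattern, t.head_position_mode, duration_s=8.0)
         for t in standard_task_set(free_duration_s=10.0)]
trials = simulate_participant(tasks, SimulationConfig(seed=3, marker_noise_sd=0.0))

results = run_noise_sweep(trials, repetitions=25, seed=7,
                          variants=("position", "orientation", "both"))
summary = summarize_sweep(results)
cols = ["variant", "multiplier", "position_sd_mm", "orientation_sd_deg",
        "mean_mm", "sd_mm", "bias_mm"]
print(summary[cols].round(3).to_string(index=False))
# Orientation noise biases the estimate toward shorter sticks (errors in the
# stick-direction regressor attenuate its coefficient) and the bias grows
# with the noise level; position noise at the base level is unbiased within
# Monte-Carlo error, but at 10x it leaks into orientation error through the
# rigid-body fit and starts to bias the length as well.
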