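"""Track head protraction through a protracted-posture trial.

Protraction — the forward displacement of the head center relative to the
thorax — is the clinically interesting output: it needs only the neck and
sternum orientations plus the stick length.  Here a trial with a sustained
25-degree forward-head offset is simulated and the per-sample protraction
table is computed.
"""

import numpy as np

from neckstick import SimulationConfig, TaskSpec, simulate_trial
from neckstick.model import protraction_series
from neckstick.frames import apply_calibration, calibrate

config = SimulationConfig(seed=7, marker_noise_sd=0.1e-3)
trial = simulate_trial(TaskSpec("static", "protracted", duration_s=6.0), config)

rec = trial.recording
rec = apply_calibration(rec, calibrate(rec, rec.meta["calibration_window"]))
table = protraction_series(rec, trial.params.l12)

expected = trial.params.l12 * np.sin(config.protraction_offset) * 1e3
print(table.iloc[:: len(table) // 8].round(2).to_string(index=False))
print(f"\nsteady-state protraction: {table['p_mm'].iloc[-1]:.2f} mm "
      f"(l12*sin(25 deg) = {expected:.2f} mm)")
# The protraction rises from 0 during the neutral lead-in to l12*sin(phi)
# once the forward-head offset is fully assumed; px/py/pz give the 3-D
# protraction vector in the calibrated frame (z = anterior).
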