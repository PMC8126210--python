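"""Synthetic trial generator: consistency with the model, noise injection, cohorts."""

import numpy as np
import pytest

from neckstick import (SimulationConfig, TaskSpec, add_orientation_noise,
                       add_position_noise, fit_length_model, fit_parameters,
                       generate_cohort, simulate_trial)
from neckstick.model import predict_head_position
from neckstick.recording import PoseSeries, TrialRecording
from tests.conftest import calibrated


class TestTaskSpec:
    def test_amplitude_outside_physiological_range_is_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("zigzag", amplitude_flexion=np.radians(85))
        with pytest.raises(ValueError):
            TaskSpec("cross", amplitude_lateral=np.radians(50))

    def test_unknown_pattern_is_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("circle")


class TestSimulateTrial:
    def test_static_zero_noise_markers_are_constant(self):
        trial = simulate_trial(TaskSpec("static", duration_s=2.0),
                               SimulationConfig(marker_noise_sd=0.0, seed=0))
        for body, pts in trial.recording.markers.items():
            assert np.ptp(pts, axis=0).max() < 1e-12, body
        # and the pose at every sample equals the calibration configuration
        for series in trial.truth.poses.values():
            assert np.allclose(series.rotations, series.rotations[0])

    def test_generator_and_model_agree_everywhere(self, noiseless_trial):
        """Measured head position equals the model prediction under the true
        parameters at every sample of a noise-free trial."""
        t = noiseless_trial
        truth = t.truth
        rs, rn, rh = (truth.poses[b].rotations for b in ("sternum", "neck", "head"))
        o_s, o_h = truth.poses["sternum"].origins, truth.poses["head"].origins
        measured = np.einsum("nji,nj->ni", rs, o_h - o_s)
        predicted = np.array([
            predict_head_position(t.params, rn[i], rs[i], rh[i])
            for i in range(0, truth.n_samples, 37)])
        assert predicted == pytest.approx(measured[::37], abs=1e-10)

    def test_zero_noise_trial_fits_back_to_truth(self, noiseless_trial):
        fit = fit_parameters(calibrated(noiseless_trial))
        assert abs(fit.params.l12 - noiseless_trial.params.l12) < 1e-9

    def test_seeded_trials_are_bit_reproducible(self):
        cfg = SimulationConfig(marker_noise_sd=2e-4, seed=123)
        a = simulate_trial(TaskSpec("zigzag", duration_s=3.0), cfg)
        b = simulate_trial(TaskSpec("zigzag", duration_s=3.0), cfg)
        for body in a.recording.markers:
            assert np.array_equal(a.recording.markers[body], b.recording.markers[body])

    def test_protracted_mode_holds_a_forward_offset(self):
        cfg = SimulationConfig(marker_noise_sd=0.0, seed=5)
        trial = simulate_trial(TaskSpec("static", "protracted", duration_s=4.0), cfg)
        from neckstick.model import protraction_series

        table = protraction_series(calibrated(trial), trial.params.l12)
        expected = trial.params.l12 * np.sin(cfg.protraction_offset) * 1e3
        assert table["p_mm"].iloc[-1] == pytest.approx(expected, rel=1e-6)
        assert table["p_mm"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def _flat_recording(n, seed=0):
    pts = np.tile(np.eye(3) * 0.03, (n, 1, 1))
    rots = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    return TrialRecording(
        time=np.arange(n) / 120.0,
        poses={b: PoseSeries(np.zeros((n, 3)), rots.copy()) for b in
               ("head", "sternum", "neck")},
        markers={b: pts.copy() for b in ("head", "sternum", "neck")})


class TestNoiseInjection:
    def test_zero_sd_returns_identical_copy(self):
        rec = _flat_recording(50)
        for noised in (add_position_noise(rec, 0.0, seed=1),
                       add_orientation_noise(rec, 0.0, seed=1)):
            for b in rec.markers:
                assert np.array_equal(noised.markers[b], rec.markers[b])
            for b in rec.poses:
                assert np.array_equal(noised.poses[b].rotations, rec.poses[b].rotations)

    def test_position_noise_has_the_requested_sd(self):
        rec = _flat_recording(12000)  # 12000*9 coordinates per body
        noised = add_position_noise(rec, 1e-3, seed=7)
        delta = noised.markers["head"] - rec.markers["head"]
        assert delta.std() == pytest.approx(1e-3, rel=0.02)
        assert abs(delta.mean()) < 5e-5

    def test_different_seeds_differ_but_share_statistics(self):
        rec = _flat_recording(2000)
        a = add_position_noise(rec, 1e-3, seed=1).markers["head"]
        b = add_position_noise(rec, 1e-3, seed=2).markers["head"]
        assert not np.array_equal(a, b)
        assert np.std(a) == pytest.approx(np.std(b), rel=0.1)

    def test_orientation_noise_stays_orthonormal_and_matches_small_angle_mean(self):
        rec = _flat_recording(30000)
        sd = np.radians(1.0)
        noised = add_orientation_noise(rec, sd, seed=3)
        rots = noised.poses["head"].rotations
        rtr = np.einsum("nji,njk->nik", rots, rots)
        assert np.abs(rtr - np.eye(3)).max() < 1e-12
        # chordal distance ||R_noisy - R||_F = 2*sqrt(2)*|sin(theta/2)| ~ sqrt(2)*theta,
        # and E|theta| = sd*sqrt(2/pi) for theta = |N(0, sd)|
        chordal = np.linalg.norm(rots - np.eye(3), axis=(1, 2))
        expected = np.sqrt(2.0) * sd * np.sqrt(2.0 / np.pi)
        assert chordal.mean() == pytest.approx(expected, rel=0.05)

    def test_noise_preserves_timing_and_labels(self):
        rec = _flat_recording(100)
        noised = add_position_noise(rec, 1e-3, seed=9)
        assert np.array_equal(noised.time, rec.time)
        assert set(noised.markers) == set(rec.markers)
        assert noised.sample_rate == rec.sample_rate


class TestCohortGeneration:
    def test_zero_scatter_puts_everyone_on_the_line(self):
        cohort = generate_cohort(8, seed=1, beta0=0.045, beta1=1.2, scatter_sd=0.0)
        x = np.array([p.anthro.length_C2C7 * 1e-2 for p in cohort])
        y = np.array([p.params.l12 for p in cohort])
        assert y == pytest.approx(1.2 * x + 0.045, abs=1e-12)
        model = fit_length_model(x, y)
        assert model.beta1 == pytest.approx(1.2, abs=1e-9)
        assert model.beta0 == pytest.approx(0.045, abs=1e-9)

    def test_large_cohort_matches_target_statistics(self):
        cohort = generate_cohort(200, seed=2)
        c2c7 = np.array([p.anthro.length_C2C7 for p in cohort])
        assert c2c7.mean() == pytest.approx(5.8, abs=0.2)

    def test_single_participant_cohort(self):
        (p,) = generate_cohort(1, seed=3)
        assert p.params.l12 > 0
        assert p.anthro.length_C2C7 < p.anthro.length_C7S2
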