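"""Least-squares parameter identification and residual summaries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neckstick import (IdentifiabilityError, NeckParameters, build_design_matrix,
                       fit_parameters, residual_stats)
from neckstick.identify import predicted_positions, solve_least_squares
from neckstick.recording import PoseSeries, TrialRecording
from neckstick.synthetic import add_position_noise
from neckstick.recording import recover_poses
from tests.conftest import calibrated


def rot(axis, deg):
    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


def recording_from_orientations(rn_list, rs_list, rh_list, params=None):
    """Forward-simulate head origins so the system is exactly consistent."""
    n = len(rn_list)
    rn, rs, rh = (np.asarray(x) for x in (rn_list, rs_list, rh_list))
    o_s = np.zeros((n, 3))
    if params is None:
        o_h = np.zeros((n, 3))
    else:
        j1 = o_s + np.einsum("nij,j->ni", rs, np.asarray(params.vs1))
        j2 = j1 + params.l12 * rn[:, :, 1]
        o_h = j2 + np.einsum("nij,j->ni", rh, np.asarray(params.v2h))
    return TrialRecording(
        time=np.arange(n) / 120.0,
        poses={"head": PoseSeries(o_h, rh), "sternum": PoseSeries(o_s, rs),
               "neck": PoseSeries(np.zeros((n, 3)), rn)})


class TestDesignMatrix:
    def test_static_identity_sample_block(self):
        rec = recording_from_orientations([np.eye(3)], [np.eye(3)], [np.eye(3)])
        a, b = build_design_matrix(rec)
        expected = np.hstack([np.eye(3), np.array([[0.0, 1.0, 0.0]]).T, np.eye(3)])
        assert a == pytest.approx(expected)
        # a single 3-row block can have rank at most 3; the identity columns
        # repeat, so a static identity sample contributes exactly rank 3
        assert np.linalg.matrix_rank(a) == 3
        assert b == pytest.approx(np.zeros(3))

    def test_three_rows_per_sample(self):
        rec = recording_from_orientations([np.eye(3)] * 17, [np.eye(3)] * 17,
                                          [np.eye(3)] * 17)
        a, b = build_design_matrix(rec)
        assert a.shape == (51, 7) and b.shape == (51,)

    def test_two_distinct_orientations_reach_full_rank(self):
        rn = [np.eye(3), rot("x", 20), rot("z", 15), np.eye(3)]
        rh = [np.eye(3), rot("x", 35), rot("z", 25), rot("y", 20)]
        rs = [np.eye(3)] * 4
        a, _ = build_design_matrix(recording_from_orientations(rn, rs, rh))
        assert np.linalg.matrix_rank(a) == 7


class TestFit:
    def test_noiseless_synthetic_recovery_is_exact(self, calibrated_battery,
                                                   short_battery):
        fit = fit_parameters(calibrated_battery)
        true = short_battery[0].params
        assert abs(fit.params.l12 - true.l12) < 1e-9
        assert np.abs(fit.params.vs1 - true.vs1).max() < 1e-9
        assert np.abs(fit.params.v2h - true.v2h).max() < 1e-9
        for s in fit.per_axis_residuals.values():
            assert abs(s.mean_error) < 1e-6 and abs(s.p5) < 1e-6 and abs(s.p95) < 1e-6

    def test_matches_normal_equations_oracle_under_noise(self, short_battery):
        """SVD solution equals (A^T A)^-1 A^T b to 1e-10; l12 within 3 mm."""
        recs = []
        for i, trial in enumerate(short_battery):
            noisy = add_position_noise(trial.recording, 1e-3, seed=100 + i)
            noisy = recover_poses(noisy, noisy.meta["reference_geometry"])
            recs.append(noisy)
        from neckstick import apply_calibration, calibrate
        recs = [apply_calibration(r, calibrate(r, r.meta["calibration_window"],
                                               spread_threshold_deg=10)) for r in recs]
        systems = [build_design_matrix(r) for r in recs]
        a = np.vstack([s[0] for s in systems])
        b = np.concatenate([s[1] for s in systems])
        theta, _ = solve_least_squares(a, b)
        oracle = np.linalg.solve(a.T @ a, a.T @ b)
        assert theta == pytest.approx(oracle, abs=1e-10)
        fit = fit_parameters(recs)
        assert abs(fit.params.l12 - short_battery[0].params.l12) < 3e-3

    def test_static_only_data_is_unidentifiable(self):
        rec = recording_from_orientations([np.eye(3)] * 50, [np.eye(3)] * 50,
                                          [np.eye(3)] * 50)
        with pytest.raises(IdentifiabilityError) as exc:
            fit_parameters(rec)
        assert exc.value.deficient_directions  # names the unexcited directions

    def test_forehead_error_maps_to_j2_error_through_v2h(self, calibrated_battery,
                                                         short_battery):
        """Perturbing the fit perturbs forehead and J2 predictions identically up
        to the constant head lever arm rotated into the sternum frame."""
        from neckstick.identify import j2_positions

        rec = calibrated_battery[1]
        true = short_battery[0].params
        off = NeckParameters(l12=true.l12 + 0.004, vs1=true.vs1,
                             v2h=np.asarray(true.v2h) + [0.002, 0, -0.001])
        d_forehead = predicted_positions(rec, off) - predicted_positions(rec, true)
        d_j2 = j2_positions(rec, off) - j2_positions(rec, true)
        rs = rec.poses["sternum"].rotations
        rh = rec.poses["head"].rotations
        rhs = np.swapaxes(rs, -1, -2) @ rh
        lever = np.einsum("nij,j->ni", rhs, np.asarray(off.v2h) - np.asarray(true.v2h))
        assert d_forehead == pytest.approx(d_j2 + lever, abs=1e-12)


class TestResidualStats:
    def test_identical_series_summarize_to_zero(self):
        x = np.random.default_rng(0).normal(size=(50, 3))
        for s in residual_stats(x, x).values():
            assert s.mean_error == s.p5 == s.p95 == 0.0

    def test_uniform_grid_mean_error(self):
        measured = np.zeros((100, 3))
        predicted = np.zeros((100, 3))
        predicted[:, 0] = np.arange(1, 101) * 1e-3  # 1..100 mm on x
        stats = residual_stats(predicted, measured)
        assert stats["x"].mean_error == pytest.approx(50.5)
        assert stats["y"].mean_error == 0.0

    def test_row_layout_has_me_and_percentiles_per_axis(self):
        from neckstick.io import residual_table

        x = np.random.default_rng(1).normal(size=(50, 3))
        table = residual_table({"P1": residual_stats(x, np.zeros_like(x))})
        expected = {f"{k}_{ax}_mm" for k in ("ME", "p5", "p95") for ax in "xyz"}
        assert expected <= set(table.columns)
        assert list(table["participant"]) == ["P1"]

    def test_empty_series_is_an_error(self):
        with pytest.raises(Exception):
            residual_stats(np.empty((0, 3)), np.empty((0, 3)))
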