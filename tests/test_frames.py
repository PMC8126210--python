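"""Frame algebra: transforms, marker-based poses, calibration, Euler angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from neckstick import (DegenerateGeometryError, FrameMismatchError, GimbalLockError,
                       MarkerTriplet, Pose, calibrate, euler_from_rotation,
                       pose_from_markers, rotation_from_euler, transform_direction,
                       transform_point)
from neckstick.frames import chordal_mean, kabsch, poses_from_marker_series
from neckstick.recording import PoseSeries, TrialRecording


def rot(axis, deg):
    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


angles_within_bounds = st.tuples(
    st.floats(-np.pi, np.pi), st.floats(-np.radians(80), np.radians(80)),
    st.floats(-np.pi, np.pi))


class TestTransforms:
    @pytest.mark.parametrize("v, r, o, expected", [
        ((0, 0, 0), np.eye(3), (0, 0, 0), (0, 0, 0)),
        ((1, 2, 3), np.eye(3), (1, 1, 1), (0, 1, 2)),       # direct substitution
        ((1, 0, 0), rot("z", 90), (0, 0, 0), (0, 1, 0)),    # hand-computed rotation
    ])
    def test_point_transform(self, v, r, o, expected):
        pose = Pose(np.asarray(o, dtype=float), r)
        assert transform_point(v, pose) == pytest.approx(np.asarray(expected), abs=1e-12)

    @pytest.mark.parametrize("v, r, expected", [
        ((0, 1, 0), np.eye(3), (0, 1, 0)),
        ((0, 0, 1), rot("x", 90), (0, -1, 0)),
    ])
    def test_direction_transform(self, v, r, expected):
        pose = Pose(np.array([5.0, 5.0, 5.0]), r)  # origin must be ignored
        assert transform_direction(v, pose) == pytest.approx(np.asarray(expected), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(angles_within_bounds, st.tuples(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)))
    def test_directions_preserve_norm(self, angles, v):
        pose = Pose(np.zeros(3), rotation_from_euler(angles))
        assert np.linalg.norm(transform_direction(v, pose)) == pytest.approx(
            np.linalg.norm(v), abs=1e-12)

    def test_frame_label_mismatch_is_rejected(self):
        pose = Pose(np.zeros(3), np.eye(3), frame_label="l", body_label="h")
        with pytest.raises(FrameMismatchError):
            transform_point((1, 0, 0), pose, v_frame="s")

    def test_round_trip_through_inverse(self):
        pose = Pose(np.array([0.3, -0.2, 0.9]), rot("z", 33) @ rot("x", -21))
        v = np.array([0.4, 0.1, -0.7])
        back = transform_point(transform_point(v, pose), pose.inverse())
        assert back == pytest.approx(v, abs=1e-12)

    def test_non_orthonormal_rotation_is_rejected(self):
        with pytest.raises(ValueError):
            Pose(np.zeros(3), np.eye(3) * 1.001)
        with pytest.raises(ValueError):  # reflection: det -1
            Pose(np.zeros(3), np.diag([1.0, 1.0, -1.0]))


class TestPoseFromMarkers:
    ref = MarkerTriplet(np.array([[0.03, 0.0, 0.0], [0.0, 0.03, 0.0], [0.0, 0.0, 0.0]]))

    def test_identity_when_markers_equal_reference(self):
        pose, rms = pose_from_markers(self.ref, self.ref)
        assert pose.rotation == pytest.approx(np.eye(3), abs=1e-12)
        assert pose.origin == pytest.approx(np.zeros(3), abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_known_transform_is_recovered_exactly(self):
        r, t = rot("z", 30), np.array([0.1, 0.0, 0.0])
        markers = MarkerTriplet(self.ref.points @ r.T + t)
        pose, rms = pose_from_markers(markers, self.ref)
        assert pose.rotation == pytest.approx(r, abs=1e-12)
        assert pose.origin == pytest.approx(t, abs=1e-12)
        assert rms < 1e-10

    def test_noisy_markers_recover_pose_within_tolerance(self, rng):
        """0.1 mm marker noise on the default 5 cm tripod -> pose within
        0.5 mm / 0.5 deg of construction."""
        from neckstick.synthetic import equilateral_reference_geometry

        ref = MarkerTriplet(equilateral_reference_geometry())
        r, t = rot("y", 40) @ rot("x", 10), np.array([0.2, -0.1, 0.3])
        for _ in range(100):
            noisy = ref.points @ r.T + t + rng.normal(0, 1e-4, (3, 3))
            pose, _ = pose_from_markers(MarkerTriplet(noisy), ref)
            assert np.linalg.norm(pose.origin - t) < 5e-4
            ang = Rotation.from_matrix(pose.rotation.T @ r).magnitude()
            assert np.degrees(ang) < 0.5

    def test_collinear_markers_are_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            MarkerTriplet(np.array([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0.0]]))

    def test_batch_fit_matches_single_sample_fit(self, rng):
        series = self.ref.points @ rot("z", 25).T + np.array([0.1, 0.2, 0.3])
        series = np.stack([series + rng.normal(0, 1e-4, (3, 3)) for _ in range(5)])
        origins, rotations, rms = poses_from_marker_series(series, self.ref.points)
        for i in range(5):
            r, t, e = kabsch(self.ref.points, series[i])
            assert rotations[i] == pytest.approx(r, abs=1e-12)
            assert origins[i] == pytest.approx(t, abs=1e-12)
            assert rms[i] == pytest.approx(e, abs=1e-12)


def _recording_with_rotations(rotations):
    rotations = np.asarray(rotations)
    n = len(rotations)
    series = PoseSeries(np.zeros((n, 3)), rotations)
    return TrialRecording(time=np.arange(n) / 120.0, poses={"head": series})


class TestCalibration:
    def test_identity_body_yields_identity_calibration(self):
        rec = _recording_with_rotations([np.eye(3)] * 10)
        cal = calibrate(rec, (0.0, 10.0))
        assert cal["head"] == pytest.approx(np.eye(3), abs=1e-12)

    def test_constant_rotation_yields_its_transpose(self):
        q = rot("z", 40) @ rot("x", 15)
        rec = _recording_with_rotations([q] * 10)
        cal = calibrate(rec, (0.0, 10.0))
        assert cal["head"] == pytest.approx(q.T, abs=1e-12)
        assert q @ cal["head"] == pytest.approx(np.eye(3), abs=1e-12)

    def test_wobble_averages_out(self, rng):
        """+/-0.5 deg wobble around Q: post-calibration mean within 1e-3 rad of I."""
        q = rot("y", 25)
        wobbles = Rotation.from_rotvec(rng.normal(0, np.radians(0.5), (200, 3))).as_matrix()
        rec = _recording_with_rotations(wobbles @ q)
        cal = calibrate(rec, (0.0, 10.0), spread_threshold_deg=5.0)
        mean_after = chordal_mean(rec.poses["head"].rotations @ cal["head"])
        assert Rotation.from_matrix(mean_after).magnitude() < 1e-3
        # chordal-mean oracle: the calibration is exactly the projected mean, transposed
        assert cal["head"] == pytest.approx(
            chordal_mean(rec.poses["head"].rotations).T, abs=1e-12)

    def test_empty_window_is_an_error(self):
        rec = _recording_with_rotations([np.eye(3)] * 10)
        with pytest.raises(ValueError):
            calibrate(rec, (5.0, 6.0))

    def test_calibration_is_idempotent(self, noiseless_trial):
        from neckstick import apply_calibration

        rec = noiseless_trial.recording
        window = rec.meta["calibration_window"]
        once = apply_calibration(rec, calibrate(rec, window))
        again = calibrate(once, window)
        for body in again:
            assert again[body] == pytest.approx(np.eye(3), abs=1e-9)

    def test_large_spread_warns(self, caplog):
        rots = Rotation.from_euler("x", np.linspace(-10, 10, 20)[:, None],
                                   degrees=True).as_matrix()
        rec = _recording_with_rotations(rots)
        with caplog.at_level("WARNING"):
            calibrate(rec, (0.0, 10.0))
        assert any("spread" in r.message for r in caplog.records)


class TestEuler:
    def test_identity_and_single_axis(self):
        assert euler_from_rotation(np.eye(3)) == pytest.approx(np.zeros(3), abs=1e-12)
        r = rotation_from_euler([np.radians(45), 0, 0])
        assert euler_from_rotation(r) == pytest.approx([np.radians(45), 0, 0], abs=1e-12)

    def test_round_trip_away_from_gimbal_lock(self, rng):
        """1000 random rotations with lateral inclination below 80 deg."""
        for _ in range(1000):
            angles = rng.uniform([-np.pi, -np.radians(80), -np.pi],
                                 [np.pi, np.radians(80), np.pi])
            r = rotation_from_euler(angles)
            assert np.linalg.norm(rotation_from_euler(euler_from_rotation(r)) - r) < 1e-9

    @pytest.mark.filterwarnings("ignore:Gimbal lock")
    def test_gimbal_lock_is_detected(self):
        r = rotation_from_euler([0.3, np.pi / 2, 0.0])
        with pytest.raises(GimbalLockError):
            euler_from_rotation(r)
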