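"""Quaternion algebra, calibration, and anatomical-angle decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cervitrack as ct
from cervitrack import kinematics
from helpers_oracle import anatomical_from_matrix, axis_angle_matrix, quat_to_matrix

VERTICAL = (0.0, 1.0, 0.0)  # +Y, subject's up


def angles_close(a, b, tol):
    return np.allclose(a.as_tuple(), b.as_tuple(), atol=tol)


class TestRelativeOrientation:
    def test_self_relative_is_identity(self):
        q = ct.Quaternion.from_axis_angle((1, 2, 3), 40.0)
        rel = ct.relative_orientation(q, ct.NeutralCalibration(q))
        assert abs(rel.w) == pytest.approx(1.0, abs=1e-12)

    def test_identity_pair(self):
        i = ct.Quaternion.identity()
        rel = ct.relative_orientation(i, ct.NeutralCalibration(i))
        assert rel == i

    def test_vertical_axis_difference_matches_matrix_oracle(self):
        # head and reference both rotated about the vertical axis: the
        # relative orientation must be the angle difference, checked by
        # independent 3x3 matrix composition
        theta, phi = 73.0, 21.0
        q = ct.Quaternion.from_axis_angle(VERTICAL, theta)
        q_ref = ct.Quaternion.from_axis_angle(VERTICAL, phi)
        rel = ct.relative_orientation(q, ct.NeutralCalibration(q_ref))
        expected = axis_angle_matrix(VERTICAL, theta - phi)
        assert np.allclose(quat_to_matrix(rel.w, rel.x, rel.y, rel.z),
                           expected, atol=1e-10)

    def test_non_unit_input_is_renormalised_with_warning(self):
        q = ct.Quaternion(2.0, 0.0, 0.0, 0.0)
        with pytest.warns(kinematics.NonUnitQuaternionWarning):
            rel = ct.relative_orientation(
                q, ct.NeutralCalibration(ct.Quaternion.identity())
            )
        assert rel == ct.Quaternion.identity()

    def test_zero_quaternion_is_a_hard_error(self):
        with pytest.raises(ValueError):
            ct.relative_orientation(
                ct.Quaternion(0, 0, 0, 0),
                ct.NeutralCalibration(ct.Quaternion.identity()),
            )


class TestDecomposeCompose:
    def test_identity_decomposes_to_zero(self):
        a = ct.decompose_angles(ct.Quaternion.identity())
        assert a.as_tuple() == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "angles",
        [(34.0, 0.0, 0.0), (0.0, 30.0, 0.0), (10.0, 20.0, 30.0),
         (-60.0, 25.0, -70.0), (80.0, -40.0, 170.0)],
    )
    def test_round_trip_is_identity(self, angles):
        a = ct.AnatomicalAngles(*angles)
        back = ct.decompose_angles(ct.compose_from_angles(a))
        assert angles_close(a, back, 1e-9)

    def test_pure_right_rotation_axis_angle(self):
        # 45 deg about the vertical axis in the right-rotation sense;
        # expectation from the independent matrix oracle
        m = axis_angle_matrix(VERTICAL, -45.0)  # right rotation = negative yaw
        fe, lat, rot = anatomical_from_matrix(m)
        assert (fe, lat) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert rot == pytest.approx(45.0, abs=1e-9)
        q = ct.Quaternion.from_axis_angle(VERTICAL, -45.0)
        got = ct.decompose_angles(q)
        assert got.rotation == pytest.approx(45.0, abs=1e-9)
        assert got.flexion_extension == pytest.approx(0.0, abs=1e-9)
        assert got.lateral_flexion == pytest.approx(0.0, abs=1e-9)

    def test_left_lateral_flexion_is_positive(self):
        a = ct.AnatomicalAngles(0.0, 30.0, 0.0)
        back = ct.decompose_angles(ct.compose_from_angles(a))
        assert back.lateral_flexion == pytest.approx(30.0, abs=1e-9)

    def test_hemisphere_invariance(self):
        q = ct.Quaternion.from_axis_angle((1, 1, 1), 50.0)
        neg = ct.Quaternion(-q.w, -q.x, -q.y, -q.z)
        assert angles_close(ct.decompose_angles(q), ct.decompose_angles(neg), 1e-9)

    def test_gimbal_proximity_warns(self):
        q = ct.compose_from_angles(ct.AnatomicalAngles(88.0, 0.0, 0.0))
        with pytest.warns(kinematics.GimbalProximityWarning):
            ct.decompose_angles(q)

    def test_matches_matrix_oracle_on_random_orientations(self):
        import warnings as _w

        rng = np.random.default_rng(42)
        quats = rng.normal(size=(1000, 4))
        for w, x, y, z in quats:
            want = anatomical_from_matrix(quat_to_matrix(w, x, y, z))
            if abs(want[0]) > 85:
                continue  # gimbal-adjacent: both representations degenerate
            with _w.catch_warnings():
                _w.simplefilter("error")
                got = ct.decompose_angles(ct.Quaternion(w, x, y, z).normalized())
            assert np.allclose(got.as_tuple(), want, atol=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        fe=st.floats(-80, 80),
        lat=st.floats(-179, 179),
        rot=st.floats(-179, 179),
    )
    def test_round_trip_property(self, fe, lat, rot):
        a = ct.AnatomicalAngles(fe, lat, rot)
        back = ct.decompose_angles(ct.compose_from_angles(a))
        assert angles_close(a, back, 1e-9)


class TestPoseStream:
    def test_non_monotonic_timestamps_rejected(self):
        t = np.array([0.0, 1 / 60, 1 / 60])
        quat = np.tile([1.0, 0, 0, 0], (3, 1))
        with pytest.raises(ValueError, match="strictly increasing"):
            ct.PoseStream(t=t, quat_wxyz=quat)

    def test_rate_mismatch_warns(self):
        t = np.arange(10) / 30.0  # 30 Hz against nominal 60
        quat = np.tile([1.0, 0, 0, 0], (10, 1))
        with pytest.warns(kinematics.RateMismatchWarning):
            ct.PoseStream(t=t, quat_wxyz=quat, nominal_rate=60.0)


class TestEstimateNeutral:
    def test_constant_stream_returns_that_orientation(self, constant_stream):
        calib = ct.estimate_neutral(constant_stream, window_s=1.0)
        q0 = ct.Quaternion(*constant_stream.quat_wxyz[0]).normalized()
        rel = ct.relative_orientation(q0, calib)
        assert abs(rel.w) == pytest.approx(1.0, abs=1e-12)

    def test_component_noise_recovers_neutral_within_tenth_degree(self):
        # Monte-Carlo: 100 seeded draws of sd-1e-3 quaternion-component noise
        q0 = ct.compose_from_angles(ct.AnatomicalAngles(12.0, -4.0, 30.0))
        base = np.array([q0.w, q0.x, q0.y, q0.z])
        t = np.arange(90) / 60.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            quat = base + rng.normal(0.0, 1e-3, size=(90, 4))
            stream = ct.PoseStream(t=t, quat_wxyz=quat, nominal_rate=60.0)
            calib = ct.estimate_neutral(stream, window_s=1.0)
            rel = ct.relative_orientation(q0, calib)
            err = 2 * np.degrees(
                np.arccos(min(1.0, abs(rel.w)))
            )
            assert err < 0.1

    def test_moving_window_raises_calibration_error(self):
        t = np.arange(120) / 60.0
        fe = 20.0 * t  # 20 deg/s drift
        quats = []
        for v in fe:
            q = ct.compose_from_angles(ct.AnatomicalAngles(v, 0.0, 0.0))
            quats.append([q.w, q.x, q.y, q.z])
        stream = ct.PoseStream(t=t, quat_wxyz=np.array(quats))
        with pytest.raises(kinematics.CalibrationError, match="deg/s"):
            ct.estimate_neutral(stream, window_s=1.0)

    def test_short_stream_rejected(self, constant_stream):
        with pytest.raises(kinematics.CalibrationError):
            ct.estimate_neutral(constant_stream, window_s=10.0)


class TestAnglesTimeseries:
    def test_neutral_only_stream_is_all_zero(self, constant_stream):
        calib = ct.estimate_neutral(constant_stream)
        series = ct.angles_timeseries(constant_stream, calib)
        assert len(series) == len(constant_stream)
        for ch in kinematics.CHANNELS:
            assert np.allclose(series.channel(ch), 0.0, atol=1e-9)

    def test_rig_rotation_trial_plateaus_at_45(self):
        stream, _ = ct.simulate_rig_trial(
            ct.RigTrialSpec(plane="rotation", angle_deg=45.0)
        )
        calib = ct.estimate_neutral(stream)
        series = ct.angles_timeseries(stream, calib)
        assert series.rotation.max() == pytest.approx(45.0, abs=1e-9)
        assert np.allclose(series.flexion_extension, 0.0, atol=1e-9)
        assert np.allclose(series.lateral_flexion, 0.0, atol=1e-9)

    def test_self_calibrated_series_starts_at_zero(self, clean_session):
        stream, _ = clean_session
        calib = ct.NeutralCalibration(ct.Quaternion(*stream.quat_wxyz[0]))
        series = ct.angles_timeseries(stream, calib)
        assert np.allclose(
            [series.flexion_extension[0], series.lateral_flexion[0],
             series.rotation[0]],
            0.0, atol=1e-9,
        )
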