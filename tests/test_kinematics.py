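import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_rigid_residual
from hmpkit.errors import (
    DegenerateGeometryError,
    EmptyPhaseError,
    GimbalWarning,
    NoCrossingError,
)
from hmpkit.kinematics import (
    PhaseInterval,
    SegmentPose,
    Trial,
    angles_at_critical_flexion,
    compose_knee_angles,
    detect_eccentric_phase,
    detect_stance,
    fit_rigid_transform,
    knee_angles_from_poses,
    lowpass,
)

TEMPLATE = np.array(
    [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.0, 0.12, 0.0], [0.03, 0.04, 0.09]]
)


def _rot(axis, deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


def make_trial(flexion, frontal=None, transverse=None, grf=None, fs=100.0, **kw):
    flexion = np.asarray(flexion, dtype=float)
    n = flexion.size
    zeros = np.zeros(n)
    return Trial(
        time_s=np.arange(n) / fs,
        flexion_deg=flexion,
        adduction_deg=zeros if frontal is None else np.asarray(frontal, float),
        int_rot_deg=zeros if transverse is None else np.asarray(transverse, float),
        grf_vertical_N=grf,
        **kw,
    )


class TestTrial:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Trial(
                time_s=np.arange(5) / 100,
                flexion_deg=np.zeros(4),
                adduction_deg=np.zeros(5),
                int_rot_deg=np.zeros(5),
            )

    def test_nonuniform_time_rejected(self):
        t = np.array([0.0, 0.01, 0.025, 0.03])
        with pytest.raises(ValueError, match="uniform"):
            Trial(
                time_s=t,
                flexion_deg=np.zeros(4),
                adduction_deg=np.zeros(4),
                int_rot_deg=np.zeros(4),
            )


class TestFitRigidTransform:
    def test_identity(self):
        pose = fit_rigid_transform(TEMPLATE, TEMPLATE)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation, 0.0, atol=1e-12)
        assert pose.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_90deg_rotation(self):
        R = _rot("z", 90.0)
        pose = fit_rigid_transform(TEMPLATE, TEMPLATE @ R.T)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(pose.rotation) - 1) / 2, -1, 1))
        )
        assert angle == pytest.approx(90.0, abs=np.degrees(1e-9))
        np.testing.assert_allclose(pose.rotation, R, atol=1e-9)

    def test_recovers_translation(self):
        t = np.array([0.5, -0.2, 1.0])
        pose = fit_rigid_transform(TEMPLATE, TEMPLATE + t)
        np.testing.assert_allclose(pose.translation, t, atol=1e-9)

    def test_residual_matches_brute_force(self, rng):
        R = _rot("y", 37.0)
        t = np.array([0.1, 0.2, -0.05])
        observed = TEMPLATE @ R.T + t + rng.normal(0, 0.002, TEMPLATE.shape)
        pose = fit_rigid_transform(TEMPLATE, observed)
        oracle = brute_force_rigid_residual(TEMPLATE, observed)
        assert pose.residual_rms == pytest.approx(oracle, abs=1e-6)

    def test_no_reflection(self):
        # mirrored observation must still yield a proper rotation
        observed = TEMPLATE * np.array([1.0, 1.0, -1.0])
        pose = fit_rigid_transform(TEMPLATE, observed)
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_transform(TEMPLATE[:2], TEMPLATE[:2])

    def test_collinear_template(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_rigid_transform(line, line)

    def test_mismatched_counts(self):
        with pytest.raises(ValueError, match="counts differ"):
            fit_rigid_transform(TEMPLATE, TEMPLATE[:3])

    def test_invariant_under_common_rigid_motion(self, rng):
        observed = TEMPLATE + rng.normal(0, 0.003, TEMPLATE.shape)
        base = fit_rigid_transform(TEMPLATE, observed).residual_rms
        R = _rot("x", 25.0) @ _rot("z", 110.0)
        t = np.array([1.0, -2.0, 0.3])
        moved = fit_rigid_transform(
            TEMPLATE @ R.T + t, observed @ R.T + t
        ).residual_rms
        assert moved == pytest.approx(base, abs=1e-9)


class TestKneeAngles:
    def test_identical_poses_zero(self):
        pose = SegmentPose(np.eye(3), np.zeros(3))
        assert knee_angles_from_poses(pose, pose) == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_flexion(self):
        thigh = SegmentPose(np.eye(3), np.zeros(3))
        shank = SegmentPose(compose_knee_angles(40.0, 0.0, 0.0), np.zeros(3))
        flex, add, rot = knee_angles_from_poses(thigh, shank)
        assert flex == pytest.approx(40.0, abs=1e-9)
        assert add == pytest.approx(0.0, abs=1e-9)
        assert rot == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=1000, deadline=None)
    @given(
        a=st.floats(-179.0, 179.0),
        b=st.floats(-79.0, 79.0),
        c=st.floats(-179.0, 179.0),
    )
    def test_round_trip(self, a, b, c):
        thigh = SegmentPose(np.eye(3), np.zeros(3))
        shank = SegmentPose(compose_knee_angles(a, b, c), np.zeros(3))
        flex, add, rot = knee_angles_from_poses(thigh, shank)
        assert flex == pytest.approx(a, abs=1e-9)
        assert add == pytest.approx(b, abs=1e-9)
        assert rot == pytest.approx(c, abs=1e-9)

    def test_gimbal_warning(self):
        thigh = SegmentPose(np.eye(3), np.zeros(3))
        shank = SegmentPose(compose_knee_angles(10.0, 90.0, 0.0), np.zeros(3))
        with pytest.warns(GimbalWarning):
            knee_angles_from_poses(thigh, shank)


class TestDetectStance:
    def test_zero_force_empty(self):
        assert detect_stance(np.zeros(500), 20.0, 1000.0) == []

    def test_rectangular_pulse(self):
        fs = 1000.0
        f = np.zeros(1000)
        f[300:550] = 1500.0  # 0.25 s pulse
        (interval,) = detect_stance(f, 20.0, fs)
        assert interval.start_index <= 300 and interval.end_index >= 550
        assert interval.start_index >= 299 and interval.end_index <= 551
        assert len(interval) / fs == pytest.approx(0.25, abs=2 / fs)

    def test_min_duration_discards(self):
        f = np.zeros(1000)
        f[100:130] = 800.0  # 0.03 s blip
        assert detect_stance(f, 20.0, 1000.0, min_duration_s=0.1) == []

    def test_stride_train_count(self, subject, small_cfg):
        from hmpkit.synthetic import generate_running_trial

        n_strides = 8
        forces, times = [], []
        offset = 0.0
        for k in range(n_strides):
            trial = generate_running_trial(subject, "neutral", k, small_cfg)
            forces.append(trial.grf_vertical_N)
            times.append(trial.time_s + offset)
            offset = times[-1][-1] + 1.0 / small_cfg.sampling_rate_mocap
        train = np.concatenate(forces)
        detected = detect_stance(train, 20.0, small_cfg.sampling_rate_mocap)
        assert len(detected) == n_strides


class TestDetectEccentricPhase:
    def test_simple_rise(self):
        phase = detect_eccentric_phase(np.array([10.0, 20.0, 30.0, 25.0]))
        assert (phase.start_index, phase.end_index) == (0, 3)
        assert phase.kind == "eccentric"

    def test_monotone_decreasing_errors(self):
        with pytest.raises(EmptyPhaseError):
            detect_eccentric_phase(np.array([30.0, 20.0, 10.0]))

    def test_within_interval(self):
        flex = np.array([50.0, 10.0, 20.0, 45.0, 30.0, 5.0])
        phase = detect_eccentric_phase(flex, within=PhaseInterval(1, 5))
        assert (phase.start_index, phase.end_index) == (1, 4)

    def test_matches_generator_peak(self, subject, small_cfg):
        from hmpkit.synthetic import generate_squat_trial

        trial = generate_squat_trial(subject, 0, small_cfg)
        phase = detect_eccentric_phase(trial.flexion_deg)
        assert phase.end_index == trial.extras["peak_index"] + 1


class TestAnglesAtCriticalFlexion:
    def test_midpoint_interpolation(self):
        trial = make_trial([30.0, 50.0], frontal=[2.0, 6.0], transverse=[1.0, 3.0])
        phase = PhaseInterval(0, 2)
        assert angles_at_critical_flexion(trial, phase, 40.0) == pytest.approx(
            (4.0, 2.0)
        )

    def test_exact_sample_hit(self):
        trial = make_trial(
            [30.0, 40.0, 55.0], frontal=[1.0, 2.0, 3.0], transverse=[4.0, 5.0, 6.0]
        )
        phase = PhaseInterval(0, 3)
        assert angles_at_critical_flexion(trial, phase, 40.0) == (2.0, 5.0)

    def test_no_crossing_names_trial(self):
        trial = make_trial([10.0, 20.0, 30.0], subject_id="S07", condition="neutral")
        with pytest.raises(NoCrossingError, match="S07"):
            angles_at_critical_flexion(trial, PhaseInterval(0, 3), 40.0)

    def test_first_rising_crossing_chosen(self):
        flex = [30.0, 50.0, 30.0, 50.0]
        trial = make_trial(flex, frontal=[0.0, 2.0, 4.0, 6.0])
        got = angles_at_critical_flexion(trial, PhaseInterval(0, 4), 40.0)
        assert got[0] == pytest.approx(1.0)  # from the first segment

    def test_noiseless_generator_returns_baseline(self, small_cfg):
        from conftest import make_subject
        from hmpkit.synthetic import generate_squat_trial

        subj = make_subject(baseline_frontal=3.0, baseline_transverse=-2.0)
        trial = generate_squat_trial(subj, 0, small_cfg)
        phase = detect_eccentric_phase(trial.flexion_deg)
        frontal, transverse = angles_at_critical_flexion(trial, phase, 40.0)
        assert frontal == pytest.approx(3.0, abs=1e-9)
        assert transverse == pytest.approx(-2.0, abs=1e-9)

    def test_invariant_to_resampling(self, small_cfg, subject):
        from hmpkit.synthetic import generate_squat_trial

        trial = generate_squat_trial(subject, 1, small_cfg)
        phase = detect_eccentric_phase(trial.flexion_deg)
        ref = angles_at_critical_flexion(trial, phase, 40.0)
        # decimate 2x: same angle-vs-flexion relation, coarser time grid
        dec = make_trial(
            trial.flexion_deg[::2],
            frontal=trial.adduction_deg[::2],
            transverse=trial.int_rot_deg[::2],
            fs=trial.sampling_rate / 2,
        )
        phase2 = detect_eccentric_phase(dec.flexion_deg)
        got = angles_at_critical_flexion(dec, phase2, 40.0)
        assert got[0] == pytest.approx(ref[0], abs=0.05)
        assert got[1] == pytest.approx(ref[1], abs=0.05)


class TestLowpass:
    def test_constant_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 12.0, 200.0), x, atol=1e-9)

    def test_passband_preserved(self):
        fs = 200.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, 12.0, fs)
        mid = slice(200, -200)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        fs = 1000.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * 60.0 * t)
        y = lowpass(x, 12.0, fs, order=4)
        mid = slice(500, -500)
        assert np.max(np.abs(y[mid])) < 0.1

    def test_cutoff_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), 120.0, 200.0)

    def test_length_preserved(self, rng):
        x = rng.normal(size=333)
        assert lowpass(x, 12.0, 100.0).size == 333
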