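"""Arm endurance/drift geometry and sit-to-stand ascent detection."""

import math

import numpy as np
import pytest

from mgce import (
    ArmSpec,
    StsSpec,
    SyntheticSpec,
    arm_angle,
    arm_angle_series,
    arm_drift,
    detect_ascend,
    gen_arm_session,
    gen_sts_session,
    hold_duration,
)
from mgce.errors import DegenerateGeometryError, NotStartedError
from mgce.limb import LOGISTIC_ASCEND_SPAN, ArmAngleSample

from conftest import make_frame, make_series


def _pose_frame(wrist, shoulder=(360.0, 380.0), t=0.0):
    return make_frame(t, {
        "shoulder_L": (shoulder[0], shoulder[1], 1.0),
        "shoulder_R": (240.0, 380.0, 1.0),
        "wrist_L": (wrist[0], wrist[1], 1.0),
        "hip_L": (330.0, 560.0, 1.0),
        "hip_R": (270.0, 560.0, 1.0),
    })


class TestArmAngle:
    def test_horizontal_abduction_is_half_pi(self):
        f = _pose_frame(wrist=(510.0, 380.0))  # wrist level with shoulder
        assert arm_angle(f, "L") == pytest.approx(math.pi / 2)

    def test_arm_at_side_is_zero(self):
        f = _pose_frame(wrist=(360.0, 530.0))  # straight down along torso
        assert arm_angle(f, "L") == pytest.approx(0.0)

    def test_45_degrees_below_horizontal(self):
        r = 150.0 / math.sqrt(2.0)
        f = _pose_frame(wrist=(360.0 + r, 380.0 + r))
        assert arm_angle(f, "L") == pytest.approx(math.pi / 4)

    def test_rotation_translation_scale_invariance(self):
        base = {
            "shoulder_L": (360.0, 380.0), "shoulder_R": (240.0, 380.0),
            "wrist_L": (480.0, 290.0), "hip_L": (330.0, 560.0), "hip_R": (270.0, 560.0),
        }
        f0 = make_frame(0.0, {k: (x, y, 1.0) for k, (x, y) in base.items()})
        a0 = arm_angle(f0, "L")
        phi, s, dx, dy = 0.7, 2.3, 41.0, -18.0
        c, sn = math.cos(phi), math.sin(phi)
        moved = {
            k: (s * (c * x - sn * y) + dx, s * (sn * x + c * y) + dy, 1.0)
            for k, (x, y) in base.items()
        }
        assert arm_angle(make_frame(0.0, moved), "L") == pytest.approx(a0, abs=1e-9)

    def test_zero_length_vector_degenerate(self):
        f = _pose_frame(wrist=(360.0, 380.0))  # wrist on the shoulder
        with pytest.raises(DegenerateGeometryError):
            arm_angle(f, "L")


def _angle_samples(theta, fps=25.0):
    t = np.arange(len(theta)) / fps
    return [ArmAngleSample(t=ti, theta_left=v, theta_right=v) for ti, v in zip(t, theta)]


class TestHoldDuration:
    def test_sustained_full_duration_capped_at_120(self):
        ang = _angle_samples(np.full(150 * 25, math.pi / 2))
        assert hold_duration(ang, "L") == pytest.approx(120.0)

    def test_drop_time_recovered(self):
        t = np.arange(150 * 25) / 25.0
        theta = np.where(t < 45.2, math.radians(80.0), math.radians(20.0))
        assert hold_duration(_angle_samples(theta), "L") == pytest.approx(45.2, abs=2 / 25.0)

    def test_momentary_dip_is_not_failure(self):
        t = np.arange(100 * 25) / 25.0
        theta = np.full_like(t, math.radians(80.0))
        dip = (t >= 50.0) & (t < 50.5)  # 0.5 s below fail angle, then recovery
        theta[dip] = math.radians(40.0)
        # window smaller than the dip so the median filter cannot erase it
        hold = hold_duration(_angle_samples(theta), "L", window_s=0.2)
        assert hold == pytest.approx(t[-1], abs=0.2)

    def test_truncation_after_failure_is_monotone(self):
        t = np.arange(120 * 25) / 25.0
        theta = np.where(t < 30.0, math.radians(80.0), math.radians(20.0))
        full = hold_duration(_angle_samples(theta), "L")
        cut = hold_duration(_angle_samples(theta[: 40 * 25]), "L")
        assert full == pytest.approx(cut, abs=1e-9)

    def test_never_started_raises(self):
        ang = _angle_samples(np.full(100, math.radians(30.0)))
        with pytest.raises(NotStartedError):
            hold_duration(ang, "L")


class TestArmDrift:
    def test_slope_times_hold_at_threshold_value(self):
        t = np.arange(125 * 25) / 25.0
        theta = math.radians(80.0) - 0.001 * t
        ang = _angle_samples(theta)
        hold = hold_duration(ang, "L")
        total, slope, pattern = arm_drift(ang, "L", hold)
        assert hold == pytest.approx(120.0)
        assert total == pytest.approx(-0.12, abs=1e-6)
        assert slope == pytest.approx(-0.001, abs=1e-9)
        assert pattern == "sustained"

    def test_control_mean_drift_value(self):
        t = np.arange(125 * 25) / 25.0
        theta = math.radians(80.0) - 0.000417 * t
        ang = _angle_samples(theta)
        total, _, _ = arm_drift(ang, "L", 120.0)
        assert total == pytest.approx(-0.05, abs=0.001)

    def test_constant_angle_zero_drift_sustained(self):
        ang = _angle_samples(np.full(125 * 25, math.radians(80.0)))
        total, slope, pattern = arm_drift(ang, "L", 120.0)
        assert total == pytest.approx(0.0, abs=1e-10)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert pattern == "sustained"

    def test_abrupt_drop_pattern(self):
        t = np.arange(150 * 25) / 25.0
        theta = np.where(t < 45.0, math.radians(80.0) - 0.0002 * t, math.radians(20.0))
        ang = _angle_samples(theta)
        hold = hold_duration(ang, "L")
        _, _, pattern = arm_drift(ang, "L", hold)
        assert pattern == "abrupt_drop"

    def test_abnormal_threshold_labels_drift(self):
        t = np.arange(125 * 25) / 25.0
        theta = math.radians(80.0) - 0.0015 * t  # -0.18 rad over 120 s
        ang = _angle_samples(theta)
        total, _, pattern = arm_drift(ang, "L", 120.0, abnormal_threshold=-0.12)
        assert total < -0.12 and pattern == "drift"

    def test_noisy_slope_recovery_within_3_se(self):
        rng = np.random.default_rng(21)
        t = np.arange(120 * 25) / 25.0
        noise = rng.normal(0, 0.003, len(t))
        theta = math.radians(80.0) - 0.001 * t + noise
        ang = _angle_samples(theta)
        _, slope, _ = arm_drift(ang, "L", 119.0)
        se = 0.003 / (np.std(t) * math.sqrt(len(t)))
        assert abs(slope - (-0.001)) < 3 * se


class TestArmGeneratorRoundTrip:
    def test_threshold_drift_recovery(self, cfg):
        s, _ = gen_arm_session(SyntheticSpec(seed=12, arm=ArmSpec(true_slope_rad_s=-0.001)))
        ang = arm_angle_series(s)
        hold = hold_duration(ang, "L")
        total, _, _ = arm_drift(ang, "L", hold)
        assert hold == pytest.approx(120.0)
        assert total == pytest.approx(-0.12, abs=0.005)

    def test_drop_session(self):
        s, _ = gen_arm_session(SyntheticSpec(
            seed=13, arm=ArmSpec(true_slope_rad_s=-0.0005, drop_time_s=45.0)))
        ang = arm_angle_series(s)
        hold = hold_duration(ang, "R")
        _, _, pattern = arm_drift(ang, "R", hold)
        assert hold == pytest.approx(45.0, abs=2 / 25.0)
        assert pattern == "abrupt_drop"

    def test_noiseless_drift_matches_truth_exactly(self):
        s, _ = gen_arm_session(SyntheticSpec(
            seed=14, arm=ArmSpec(true_slope_rad_s=-0.0008, noise_sd_px=0.0)))
        ang = arm_angle_series(s)
        total, slope, _ = arm_drift(ang, "L", 120.0)
        assert slope == pytest.approx(-0.0008, abs=1e-6)
        assert total == pytest.approx(-0.096, abs=1e-4)


class TestSitToStand:
    def test_logistic_rise_timing(self):
        for true_ascend, fps in ((0.8, 25.0), (1.2, 25.0), (2.0, 30.0), (3.0, 25.0)):
            spec = SyntheticSpec(seed=15, fps=fps, sts=StsSpec(true_ascend_s=true_ascend))
            s, _ = gen_sts_session(spec)
            res = detect_ascend(s)
            assert res.able_to_stand
            assert res.ascend_time == pytest.approx(true_ascend, abs=0.2)

    def test_flat_trajectory_unable_to_stand(self):
        s, _ = gen_sts_session(SyntheticSpec(seed=16, sts=StsSpec(able=False)))
        res = detect_ascend(s)
        assert not res.able_to_stand and res.ascend_time is None

    def test_missing_head_sets_partial_view(self):
        s, _ = gen_sts_session(SyntheticSpec(seed=17, sts=StsSpec(include_head=False)))
        assert detect_ascend(s).partial_view is True

    def test_ascend_span_constant_matches_quadrature(self):
        # the above-10%-velocity span of a logistic: 4 f (1-f) = 0.1
        f = (1 - math.sqrt(0.9)) / 2
        span = 2 * abs(math.log(f / (1 - f)))
        assert LOGISTIC_ASCEND_SPAN == pytest.approx(span, abs=1e-4)
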