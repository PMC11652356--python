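"""Limb motor metrics: arm-extension endurance/drift and sit-to-stand timing.

Arm endurance: the participant abducts both arms to roughly 90 degrees with
elbows extended, seated, for up to 2 minutes. The arm-torso angle (radians,
between the shoulder->wrist vector and the torso axis) is tracked per arm;
the hold time is capped at 120 s and the downward drift is the least-squares
slope over the held window times the hold time, so the summary is in radians
over the test (negative = downward). Neuromuscular fatigue shows either a
continuous linear drift or an abrupt drop of the arm.

Sit-to-stand: the ascending phase is the interval around peak upward hip
velocity where upward velocity exceeds 10% of its peak; its length is the
ascending time. Inability to stand is detected from the total hip rise
relative to trunk length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .data import LandmarkFrame, LandmarkSeries
from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    NotStartedError,
)
from .filters import fit_linear_drift, rolling_median, smooth_series

ArmPattern = Literal["sustained", "drift", "abrupt_drop"]


@dataclass(frozen=True)
class ArmAngleSample:
    t: float
    theta_left: float   # radians in [0, pi]
    theta_right: float


class ArmSideResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    hold_time: float      # seconds, <= cap
    drift_total: float    # radians over the held window (slope x hold time)
    drift_slope: float    # radians/s
    pattern: ArmPattern


class ArmResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    left: ArmSideResult
    right: ArmSideResult
    seated_stable: bool = True  # hip-y stability proxy for the seated requirement


class SitToStandResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    able_to_stand: bool
    ascend_time: Optional[float] = None  # present iff able_to_stand
    partial_view: bool = False

    def model_post_init(self, __context) -> None:
        if self.able_to_stand != (self.ascend_time is not None):
            raise ValueError("ascend_time must be present iff able_to_stand")


def _mid(frame: LandmarkFrame, a: str, b: str) -> tuple[float, float] | None:
    pa, pb = frame.points.get(a), frame.points.get(b)
    if pa is None or pb is None:
        return None
    return ((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)


def arm_angle(frame: LandmarkFrame, side: Literal["L", "R"]) -> float:
    """Angle (radians) between the shoulder->wrist vector and the torso axis.

    The torso axis runs mid-shoulder -> mid-hip; an arm hanging along the
    torso reads 0, full horizontal abduction reads ~pi/2. Invariant to
    translation, uniform scaling and global rotation of the landmarks.
    """
    sh = frame.points.get(f"shoulder_{side}")
    wr = frame.points.get(f"wrist_{side}")
    mid_sh = _mid(frame, "shoulder_L", "shoulder_R")
    mid_hip = _mid(frame, "hip_L", "hip_R")
    if sh is None or wr is None or mid_sh is None or mid_hip is None:
        raise InsufficientDataError(f"missing landmarks for arm angle, side {side}")
    ax, ay = wr[0] - sh[0], wr[1] - sh[1]
    tx, ty = mid_hip[0] - mid_sh[0], mid_hip[1] - mid_sh[1]
    na, nt = math.hypot(ax, ay), math.hypot(tx, ty)
    if na == 0 or nt == 0:
        raise DegenerateGeometryError("zero-length arm or torso vector")
    cross = ax * ty - ay * tx
    dot = ax * tx + ay * ty
    return math.atan2(abs(cross), dot)  # in [0, pi]


def arm_angle_series(series: LandmarkSeries) -> list[ArmAngleSample]:
    out = []
    for f in series.frames:
        try:
            out.append(ArmAngleSample(t=f.t, theta_left=arm_angle(f, "L"),
                                      theta_right=arm_angle(f, "R")))
        except InsufficientDataError:
            continue
    if not out:
        raise InsufficientDataError("no frame with both arms measurable")
    return out


def _side_arrays(angles: Sequence[ArmAngleSample], side: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([a.t for a in angles])
    v = np.array([a.theta_left if side == "L" else a.theta_right for a in angles])
    return t, v


def hold_duration(
    angles: Sequence[ArmAngleSample],
    side: Literal["L", "R"],
    fail_angle: float = math.radians(60.0),
    cap_s: float = 120.0,
    start_angle: float = math.radians(70.0),
    sustain_s: float = 1.0,
    window_s: float = 0.5,
) -> float:
    """Seconds from exercise start until abduction is lost, capped.

    Start = first sample with theta >= start_angle. Failure = first time the
    median-filtered angle falls below ``fail_angle`` and stays below for at
    least ``sustain_s`` (a momentary dip is not a failure). The median alone
    is used so an abrupt drop keeps its sharp edge and the crossing time is
    unbiased.
    """
    t, v = _side_arrays(angles, side)
    if len(t) < 3 or t[-1] - t[0] < 1.0:
        raise InsufficientDataError("arm hold needs at least 1 s of samples")
    started = np.nonzero(v >= start_angle)[0]
    if len(started) == 0:
        raise NotStartedError(f"abduction never reached start angle {start_angle:.2f} rad")
    i0 = int(started[0])
    sm = rolling_median(t, v, window_s)
    below = sm < fail_angle
    t_fail = None
    i = i0
    n = len(t)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        # below-threshold run spans [i, j); a run reaching the data end is
        # treated as sustained (no recovery observed)
        if j >= n or t[j - 1] - t[i] >= sustain_s:
            t_fail = t[i]
            break
        i = j
    if t_fail is None:
        hold = t[-1] - t[i0]
    else:
        hold = t_fail - t[i0]
    return float(min(hold, cap_s))


def arm_drift(
    angles: Sequence[ArmAngleSample],
    side: Literal["L", "R"],
    hold_time: float,
    cap_s: float = 120.0,
    abrupt_drop_rad: float = 0.3,
    abnormal_threshold: float | None = None,
    start_angle: float = math.radians(70.0),
) -> tuple[float, float, ArmPattern]:
    """(drift_total, slope, pattern) over the held window.

    drift_total = OLS slope x hold_time, radians over the test (negative =
    downward). Pattern: "abrupt_drop" when the hold ended early and the final
    1-s mean angle sits > ``abrupt_drop_rad`` below the fitted line;
    "drift" when drift_total is more negative than ``abnormal_threshold``;
    else "sustained".
    """
    if hold_time <= 0:
        raise InsufficientDataError("hold_time must be positive")
    t, v = _side_arrays(angles, side)
    started = np.nonzero(v >= start_angle)[0]
    if len(started) == 0:
        raise NotStartedError("abduction never started")
    t0 = t[int(started[0])]
    held = (t >= t0) & (t <= t0 + hold_time)
    if held.sum() < 3:
        raise InsufficientDataError("too few samples in the held window")
    slope, intercept, _ = fit_linear_drift(t[held], v[held])
    drift_total = slope * hold_time

    pattern: ArmPattern = "sustained"
    if hold_time < cap_s - 1e-9:
        tail = t >= t[-1] - 1.0
        tail_mean = float(np.mean(v[tail]))
        predicted = slope * float(np.mean(t[tail])) + intercept
        if tail_mean < predicted - abrupt_drop_rad:
            pattern = "abrupt_drop"
    if pattern == "sustained" and abnormal_threshold is not None and drift_total < abnormal_threshold:
        pattern = "drift"
    return float(drift_total), float(slope), pattern


def seated_stable(series: LandmarkSeries, max_rel_shift: float = 0.25) -> bool:
    """Hip-y stability proxy for the seated requirement during the arm hold."""
    t, _, y, _ = series.coords("hip_L")
    t2, _, y2, _ = series.coords("hip_R")
    if len(y) < 3 or len(y2) < 3:
        return True  # cannot assess; visibility QC handles absence
    trunk = _trunk_length(series)
    if trunk is None or trunk <= 0:
        return True
    shift = max(float(np.ptp(smooth_series(t, y, 0.5))), float(np.ptp(smooth_series(t2, y2, 0.5))))
    return shift / trunk <= max_rel_shift


def _trunk_length(series: LandmarkSeries) -> float | None:
    """Median mid-shoulder -> mid-hip distance, px."""
    ds = []
    for f in series.frames:
        ms = _mid(f, "shoulder_L", "shoulder_R")
        mh = _mid(f, "hip_L", "hip_R")
        if ms is not None and mh is not None:
            ds.append(math.hypot(ms[0] - mh[0], ms[1] - mh[1]))
    if not ds:
        return None
    return float(np.median(ds))


def analyze_arm(series: LandmarkSeries, cfg: dict, abnormal_threshold: float | None = None) -> ArmResult:
    angles = arm_angle_series(series)
    start = math.radians(cfg["arm.start_angle_deg"])
    fail = math.radians(cfg["arm.fail_angle_deg"])
    sides = {}
    for side in ("L", "R"):
        hold = hold_duration(
            angles, side, fail_angle=fail, cap_s=cfg["arm.cap_s"],
            start_angle=start, sustain_s=cfg["arm.sustain_s"],
        )
        drift_total, slope, pattern = arm_drift(
            angles, side, hold, cap_s=cfg["arm.cap_s"],
            abrupt_drop_rad=cfg["arm.abrupt_drop_rad"],
            abnormal_threshold=abnormal_threshold, start_angle=start,
        )
        sides[side] = ArmSideResult(
            hold_time=hold, drift_total=drift_total, drift_slope=slope, pattern=pattern
        )
    return ArmResult(left=sides["L"], right=sides["R"], seated_stable=seated_stable(series))


#: Above-10%-of-peak-velocity span of a logistic rise, in units of its time
#: scale tau: solving 4f(1-f) = 0.1 gives x = +/-3.63712, so span = 7.27424 tau.
LOGISTIC_ASCEND_SPAN = 7.2737858

def detect_ascend(
    series: LandmarkSeries,
    velocity_frac: float = 0.10,
    min_rise_frac: float = 0.5,
    window_s: float = 0.12,
) -> SitToStandResult:
    """Ascending-phase timing from the smoothed mid-hip vertical trajectory.

    Upward velocity is the derivative of the (image-inverted) hip height;
    the ascending phase is the maximal interval around the velocity peak
    where upward velocity exceeds ``velocity_frac`` of that peak. Standing is
    achieved when the total hip rise reaches ``min_rise_frac`` of the trunk
    length (mid-shoulder to mid-hip), a displacement proxy available without
    calibration.
    """
    t, h = [], []
    for f in series.frames:
        mh = _mid(f, "hip_L", "hip_R")
        if mh is not None:
            t.append(f.t)
            h.append(-mh[1])  # image y grows downward; height = -y
    if len(t) < 5:
        raise InsufficientDataError("too few frames with both hips visible")
    t = np.array(t)
    h = smooth_series(np.array(t), np.array(h), window_s)
    partial = series.coverage("head_top") < 0.9

    trunk = _trunk_length(series)
    rise = float(h[-1] - h[0])
    if trunk is None or trunk <= 0 or rise < min_rise_frac * trunk:
        return SitToStandResult(able_to_stand=False, ascend_time=None, partial_view=partial)

    v = np.gradient(h, t)
    peak_i = int(np.argmax(v))
    peak = float(v[peak_i])
    if peak <= 0:
        return SitToStandResult(able_to_stand=False, ascend_time=None, partial_view=partial)
    thresh = velocity_frac * peak
    lo = peak_i
    while lo > 0 and v[lo - 1] > thresh:
        lo -= 1
    hi = peak_i
    while hi < len(v) - 1 and v[hi + 1] > thresh:
        hi += 1
    return SitToStandResult(
        able_to_stand=True,
        ascend_time=float(t[hi] - t[lo]),
        partial_view=partial,
    )
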