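"""Lip-motion acceleration during counting, a facial-weakness proxy.

The upper-lip vertical position is normalized by mouth width (robust to
camera distance and to head pitch) and its second time derivative is taken
by central finite differences at the native frame rate. The summary is the
mean absolute acceleration over the located counting window, in normalized
distance per second squared: weak orofacial muscles move the lips with lower
acceleration. The second derivative annihilates constant drifts in the
normalized position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data import LandmarkSeries
from .errors import InsufficientDataError, NonUniformSamplingError
from .filters import second_central_difference, smooth_series

MIN_MOUTH_WIDTH_PX = 3.0


@dataclass(frozen=True)
class MouthMotionSample:
    t: float
    u: float        # upper-lip y / mouth width (unitless)
    opening: float  # (lip_lower y - lip_upper y) / mouth width


@dataclass(frozen=True)
class MouthSeries:
    samples: tuple[MouthMotionSample, ...]
    n_dropped: int  # frames rejected for mouth width below the pixel floor


def mouth_motion_series(
    series: LandmarkSeries,
    normalizer: Literal["mouth_width", "interocular"] = "mouth_width",
) -> MouthSeries:
    """Normalized lip positions per usable frame.

    Frames whose normalizing distance is under ``MIN_MOUTH_WIDTH_PX`` are
    dropped and counted.
    """
    samples: list[MouthMotionSample] = []
    dropped = 0
    for f in series.frames:
        up, lo = f.points.get("lip_upper"), f.points.get("lip_lower")
        if up is None or lo is None:
            continue
        if normalizer == "mouth_width":
            a, b = f.points.get("mouth_left"), f.points.get("mouth_right")
        else:
            a, b = f.points.get("eye_inner_L"), f.points.get("eye_inner_R")
        if a is None or b is None:
            continue
        width = abs(b[0] - a[0])
        if width < MIN_MOUTH_WIDTH_PX:
            dropped += 1
            continue
        samples.append(MouthMotionSample(t=f.t, u=up[1] / width, opening=(lo[1] - up[1]) / width))
    if not samples:
        raise InsufficientDataError("no usable frames for mouth motion")
    return MouthSeries(samples=tuple(samples), n_dropped=dropped)


def mean_abs_acceleration(
    samples: Sequence[MouthMotionSample],
    window: tuple[float, float],
    smooth_window_s: float = 0.0,
    stat: Literal["mean_abs", "sd"] = "mean_abs",
) -> float:
    """Mean |u''| (or SD of u'') over a time window, 1/s^2.

    u'' is the 3-point central second difference of the normalized upper-lip
    position at the native frame period. Optional pre-smoothing
    (``smooth_window_s``) suppresses landmark jitter, which second
    differences otherwise amplify quadratically; it is off by default
    because it also attenuates genuine articulation frequencies.
    """
    t = np.array([s.t for s in samples])
    u = np.array([s.u for s in samples])
    t0, t1 = window
    pad = 1  # one sample each side so the stencil covers the window edges
    inside = np.nonzero((t >= t0) & (t <= t1))[0]
    if len(inside) < 3:
        raise InsufficientDataError("fewer than 3 samples inside the window")
    lo = max(int(inside[0]) - pad, 0)
    hi = min(int(inside[-1]) + pad, len(t) - 1)
    tw, uw = t[lo : hi + 1], u[lo : hi + 1]
    if tw[-1] - tw[0] < 0.5:
        raise InsufficientDataError("acceleration window must span at least 0.5 s")
    dts = np.diff(tw)
    dt = float(np.median(dts))
    if np.any(dts > 2.0 * dt + 1e-9):
        raise NonUniformSamplingError("sampling gaps exceed 2 frame periods; resample first")
    if smooth_window_s > 0:
        uw = smooth_series(tw, uw, smooth_window_s)
    acc = second_central_difference(uw, dt)
    acc_t = tw[1:-1]
    sel = (acc_t >= t0) & (acc_t <= t1)
    if not np.any(sel):
        raise InsufficientDataError("no interior stencil points inside the window")
    a = acc[sel]
    if stat == "sd":
        return float(np.std(a))
    return float(np.mean(np.abs(a)))
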