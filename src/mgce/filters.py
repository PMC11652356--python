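"""Shared numerical primitives: smoothing, least-squares drift, differences.

Landmark traces carry frame-to-frame detector jitter; every fatigue metric
first passes through a moving-median (spike rejection: blinks, single-frame
detector failures) followed by a moving-average (residual jitter) over the
same time window. Endpoints use shrunken windows so output length equals
input length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError


def _window_samples(t: np.ndarray, window_s: float) -> int:
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise DegenerateInputError("non-increasing time values")
    w = max(1, int(round(window_s / dt)))
    return w if w % 2 == 1 else w + 1


def smooth_series(t: np.ndarray, v: np.ndarray, window_s: float) -> np.ndarray:
    """Moving median then moving average over ``window_s`` seconds.

    Output is aligned with the input; endpoints use shrunken (one-sided)
    windows. ``window_s`` below one sample period is the identity.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise InsufficientDataError("smoothing needs at least 3 samples")
    if window_s <= 0:
        return v.copy()
    w = _window_samples(t, window_s)
    s = pd.Series(v)
    s = s.rolling(w, center=True, min_periods=1).median()
    s = s.rolling(w, center=True, min_periods=1).mean()
    return s.to_numpy()


def rolling_median(t: np.ndarray, v: np.ndarray, window_s: float) -> np.ndarray:
    """Moving median alone over ``window_s``; keeps step edges sharp.

    Used where a threshold-crossing *time* matters: the follow-up moving
    average would turn a step into a ramp and bias the crossing.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise InsufficientDataError("smoothing needs at least 3 samples")
    if window_s <= 0:
        return v.copy()
    w = _window_samples(t, window_s)
    return pd.Series(v).rolling(w, center=True, min_periods=1).median().to_numpy()


def fit_linear_drift(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares v = slope*t + intercept; returns (slope, intercept, r2).

    r2 is clipped to [0, 1]; a constant series (zero total variance) fits its
    own mean exactly and reports r2 = 1.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("linear fit needs at least 3 samples")
    if np.ptp(t) == 0:
        raise DegenerateInputError("all time values equal; slope undefined")
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(v - v.mean(), v - v.mean()))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, abs(float(v.mean()))) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def second_central_difference(v: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative by the 3-point central stencil, length n-2."""
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise InsufficientDataError("second difference needs at least 3 samples")
    if dt <= 0:
        raise DegenerateInputError("dt must be positive")
    return (v[2:] - 2.0 * v[1:-1] + v[:-2]) / (dt * dt)
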