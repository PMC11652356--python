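"""Lid-fatigue quantification during sustained upgaze.

The palpebral aperture (vertical lid separation, px) is tracked over the
exercise; fatigable ptosis shows either a smooth linear droop of the upper
lid or a chaotic open/shut struggle to maintain upgaze. The summary score is
the retained aperture: robust minimum of the filtered aperture divided by
its maximum, in percent. Being a ratio, it is invariant to camera distance.
Filtered control recordings vary by at most ~4%, so controls score >= ~96%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .data import LandmarkSeries
from .errors import DegenerateInputError, InsufficientDataError
from .filters import fit_linear_drift, smooth_series

PtosisPattern = Literal["stable", "linear_fatigue", "unstable"]


@dataclass(frozen=True)
class EyeAperture:
    """Per-frame vertical eye geometry, pixels (y grows downward)."""

    t: float
    aperture: float               # lid_lower y - lid_upper y, clamped >= 0
    eye_width: float              # |outer canthus x - inner canthus x|
    iris_margin: Optional[float]  # iris_bottom y - lid_upper y, if iris seen
    clamped: bool = False         # lids crossed in this frame


class PtosisEyeResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    retained_pct: float
    drift_slope: float  # px/s, negative = closing
    fit_r2: float
    pattern: PtosisPattern


class PtosisResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    left: Optional[PtosisEyeResult] = None
    right: Optional[PtosisEyeResult] = None
    head_tilt_flag: Optional[bool] = None  # None = landmarks absent, indeterminate


def compute_eye_apertures(series: LandmarkSeries, eye: Literal["L", "R"]) -> list[EyeAperture]:
    """One sample per frame where the lid pair and both canthi are present."""
    out: list[EyeAperture] = []
    up_n, lo_n = f"lid_upper_{eye}", f"lid_lower_{eye}"
    in_n, out_n = f"eye_inner_{eye}", f"eye_outer_{eye}"
    iris_n = f"iris_bottom_{eye}"
    for f in series.frames:
        up, lo = f.points.get(up_n), f.points.get(lo_n)
        inner, outer = f.points.get(in_n), f.points.get(out_n)
        if up is None or lo is None or inner is None or outer is None:
            continue
        width = abs(outer[0] - inner[0])
        if width <= 0:
            continue
        ap = lo[1] - up[1]
        clamped = ap < 0
        iris = f.points.get(iris_n)
        out.append(
            EyeAperture(
                t=f.t,
                aperture=max(ap, 0.0),
                eye_width=width,
                iris_margin=(iris[1] - up[1]) if iris is not None else None,
                clamped=clamped,
            )
        )
    if not out:
        raise InsufficientDataError(f"no usable frames for eye {eye}")
    return out


def _filtered_aperture(apertures: Sequence[EyeAperture], window_s: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([a.t for a in apertures])
    v = np.array([a.aperture for a in apertures])
    return t, smooth_series(t, v, window_s)


def retained_aperture_pct(
    apertures: Sequence[EyeAperture],
    window_s: float = 0.5,
    robust_q: float = 0.05,
) -> float:
    """Robust minimum over robust maximum of the filtered aperture, percent.

    The extremes are the ``robust_q`` and ``1 - robust_q`` quantiles of the
    filtered series: a residual blink frame cannot set the minimum, and
    two-sided detector jitter cannot inflate the maximum (the raw maximum of
    a jittered series is upward-biased, which would deflate the score).
    """
    t = np.array([a.t for a in apertures])
    if len(t) < 3 or t[-1] - t[0] < 2.0:
        raise InsufficientDataError("retained aperture needs at least 2 s of data")
    _, sm = _filtered_aperture(apertures, window_s)
    mx = float(np.quantile(sm, 1.0 - robust_q))
    if mx <= 0:
        raise DegenerateInputError("maximum filtered aperture is zero")
    rmin = float(np.quantile(sm, robust_q))
    return float(np.clip(rmin / mx * 100.0, 0.0, 100.0))


def classify_ptosis_pattern(
    apertures: Sequence[EyeAperture],
    noise_pct: float = 4.0,
    r2_min: float = 0.6,
    window_s: float = 0.5,
    robust_q: float = 0.05,
) -> PtosisPattern:
    """stable (within noise), linear_fatigue (good negative line fit), else unstable."""
    retained = retained_aperture_pct(apertures, window_s=window_s, robust_q=robust_q)
    if 100.0 - retained <= noise_pct:
        return "stable"
    t, sm = _filtered_aperture(apertures, window_s)
    slope, _, r2 = fit_linear_drift(t, sm)
    if slope < 0 and r2 >= r2_min:
        return "linear_fatigue"
    return "unstable"


def detect_head_tilt(
    series: LandmarkSeries,
    rel_change_max: float = 0.15,
    window_s: float = 0.5,
) -> Optional[bool]:
    """Backward head tilt compensating for ptosis.

    Detected as a monotone change of the smoothed chin-to-head-top vertical
    extent exceeding ``rel_change_max`` relative to its initial 2-s median
    (tilting the head back foreshortens the face in the image). Returns None
    (indeterminate) when the landmarks are absent.
    """
    t, ext = [], []
    for f in series.frames:
        chin, top = f.points.get("chin"), f.points.get("head_top")
        if chin is not None and top is not None:
            t.append(f.t)
            ext.append(abs(chin[1] - top[1]))
    if len(t) < 3:
        return None
    t = np.array(t)
    ext = np.array(ext)
    sm = smooth_series(t, ext, window_s)
    base = float(np.median(sm[t - t[0] <= 2.0]))
    if base <= 0:
        return None
    slope, _, r2 = fit_linear_drift(t, sm)
    total = slope * (t[-1] - t[0])
    # r2 gate: the change must be a trend, not symmetric wobble
    return bool(abs(total) / base > rel_change_max and r2 >= 0.5)


def analyze_ptosis(series: LandmarkSeries, cfg: dict) -> PtosisResult:
    """Full per-session ptosis analysis under a configuration mapping."""
    per_eye: dict[str, Optional[PtosisEyeResult]] = {"L": None, "R": None}
    for eye in ("L", "R"):
        try:
            aps = compute_eye_apertures(series, eye)  # type: ignore[arg-type]
        except InsufficientDataError:
            continue
        window = cfg["ptosis.window_s"]
        q = cfg["ptosis.robust_q"]
        retained = retained_aperture_pct(aps, window_s=window, robust_q=q)
        t, sm = _filtered_aperture(aps, window)
        slope, _, r2 = fit_linear_drift(t, sm)
        pattern = classify_ptosis_pattern(
            aps, noise_pct=cfg["ptosis.noise_pct"], r2_min=cfg["ptosis.r2_min"],
            window_s=window, robust_q=q,
        )
        per_eye[eye] = PtosisEyeResult(
            retained_pct=retained, drift_slope=slope, fit_r2=r2, pattern=pattern
        )
    if per_eye["L"] is None and per_eye["R"] is None:
        raise InsufficientDataError("neither eye usable for ptosis analysis")
    tilt = detect_head_tilt(
        series, rel_change_max=cfg["ptosis.head_tilt_rel_change"], window_s=cfg["ptosis.window_s"]
    )
    return PtosisResult(left=per_eye["L"], right=per_eye["R"], head_tilt_flag=tilt)
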