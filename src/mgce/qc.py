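"""Recording-quality screening before any metric is computed.

A recording is excluded when the region of interest is not reliably visible,
the eye is imaged at too few pixels to resolve lid motion, or the frame rate
is unsupported / unstable. Operating on landmark series rather than raw
video, "too close to camera" and "poor illumination" are proxied by missing
or low-confidence landmarks.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .data import Exercise, LandmarkSeries

QCReason = Literal[
    "too_close",
    "low_resolution",
    "low_contrast_or_confidence",
    "low_audio",
    "roi_not_visible",
    "fps_unsupported",
]

#: Landmarks that must be visible for each exercise to be analyzable.
REQUIRED_LANDMARKS: dict[str, tuple[str, ...]] = {
    "ptosis": ("lid_upper_L", "lid_lower_L", "lid_upper_R", "lid_lower_R",
               "eye_inner_L", "eye_outer_L", "eye_inner_R", "eye_outer_R"),
    "diplopia": ("eye_inner_L", "eye_outer_L", "eye_inner_R", "eye_outer_R",
                 "iris_center_L", "iris_center_R"),
    "arm": ("shoulder_L", "shoulder_R", "wrist_L", "wrist_R", "hip_L", "hip_R", "chin"),
    "sit_to_stand": ("hip_L", "hip_R", "shoulder_L", "shoulder_R"),
    "count50": ("lip_upper", "lip_lower", "mouth_left", "mouth_right"),
    "single_breath": (),
}


class QCReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    exercise: Exercise
    passed: bool
    reasons: tuple[QCReason, ...] = ()
    details: dict[str, str] = {}

    @model_validator(mode="after")
    def _consistent(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must equal (reasons empty)")
        return self

    @classmethod
    def ok(cls, exercise: str) -> "QCReport":
        return cls(exercise=exercise, passed=True)

    @classmethod
    def fail(cls, exercise: str, details: dict[str, str]) -> "QCReport":
        return cls(
            exercise=exercise,
            passed=False,
            reasons=tuple(details.keys()),
            details=dict(details),
        )


def check_eye_resolution(series: LandmarkSeries, min_aperture_px: float = 7.0) -> QCReport:
    """Fail when the eye subtends too few pixels to resolve lid motion.

    The median vertical lid aperture over the first 2 s must reach
    ``min_aperture_px`` for at least one eye.
    """
    t0 = series.frames[0].t if series.frames else 0.0
    best = None
    for side in ("L", "R"):
        apertures = []
        for f in series.frames:
            if f.t - t0 > 2.0:
                break
            up = f.points.get(f"lid_upper_{side}")
            lo = f.points.get(f"lid_lower_{side}")
            if up is not None and lo is not None:
                apertures.append(lo[1] - up[1])
        if apertures:
            med = float(np.median(apertures))
            best = med if best is None else max(best, med)
    if best is None:
        return QCReport.fail(series.exercise, {"roi_not_visible": "no eyelid landmark pair present"})
    if best < min_aperture_px:
        return QCReport.fail(
            series.exercise,
            {"low_resolution": f"median lid aperture {best:.1f} px < {min_aperture_px} px"},
        )
    return QCReport.ok(series.exercise)


def check_roi_visibility(
    series: LandmarkSeries,
    exercise: str | None = None,
    min_confidence: float = 0.5,
    min_coverage: float = 0.9,
) -> QCReport:
    """Every required landmark must be confidently present in >= min_coverage of frames."""
    exercise = exercise or series.exercise
    required = REQUIRED_LANDMARKS[exercise]
    missing = {}
    for name in required:
        cov = series.coverage(name, min_confidence=min_confidence)
        if cov < min_coverage:  # boundary inclusive: cov == min_coverage passes
            missing[name] = cov
    if missing:
        desc = ", ".join(f"{n} ({c:.0%})" for n, c in missing.items())
        return QCReport.fail(exercise, {"roi_not_visible": f"insufficient coverage: {desc}"})
    return QCReport.ok(exercise)


def check_fps(series: LandmarkSeries, supported: Sequence[float] = (25.0, 30.0)) -> QCReport:
    """Nominal fps must be supported and inter-frame gaps stable.

    Fails when >5% of gaps deviate from the nominal period by more than 50%
    (dropped or duplicated frames).
    """
    if not any(abs(series.fps - s) < 1e-9 for s in supported):
        return QCReport.fail(
            series.exercise, {"fps_unsupported": f"nominal fps {series.fps} not in {sorted(supported)}"}
        )
    ts = series.times
    if len(ts) >= 2:
        gaps = np.diff(ts)
        period = 1.0 / series.fps
        bad = np.abs(gaps - period) > 0.5 * period
        frac = float(np.mean(bad))
        if frac > 0.05:
            return QCReport.fail(
                series.exercise,
                {"fps_unsupported": f"{frac:.0%} of inter-frame gaps deviate >50% from 1/fps"},
            )
    return QCReport.ok(series.exercise)


def run_qc(series: LandmarkSeries, cfg: dict) -> QCReport:
    """Combined per-exercise QC under a configuration mapping."""
    reports = [
        check_roi_visibility(
            series,
            min_confidence=cfg["qc.min_confidence"],
            min_coverage=cfg["qc.min_coverage"],
        ),
        check_fps(series, supported=cfg["qc.supported_fps"]),
    ]
    if series.exercise in ("ptosis", "diplopia"):
        reports.append(check_eye_resolution(series, min_aperture_px=cfg["qc.min_aperture_px"]))
    details: dict[str, str] = {}
    for r in reports:
        for reason, text in r.details.items():
            details.setdefault(reason, text)
    if details:
        return QCReport.fail(series.exercise, details)
    return QCReport.ok(series.exercise)
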