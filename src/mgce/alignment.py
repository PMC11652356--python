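"""Horizontal ocular misalignment during sustained eccentric gaze.

Each iris position is reduced to a barycentric coordinate within its own
palpebral fissure: 0 at the nasal canthus, 1 at the temporal canthus. After
mirroring the left eye onto a common axis, conjugate (normal, yoked) gaze
cancels exactly and the inter-eye difference indexes misalignment, with 0
meaning aligned regardless of gaze direction. Progressive misalignment is
summarized by the least-squares slope of that difference times the exercise
duration. Differences below the measurement floor (default 0.05, the
resolvability limit of consumer video) are reported but flagged
indeterminate. Vertical misalignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .data import LandmarkFrame, LandmarkSeries, TranscriptWords
from .errors import DegenerateInputError, InsufficientDataError, LowResolutionError
from .filters import fit_linear_drift

DEFAULT_DIPLOPIA_KEYWORDS = ("double", "two of", "diplopia", "split")

#: Minimum horizontal canthus separation (px) to resolve iris position.
MIN_EYE_WIDTH_PX = 3.0


@dataclass(frozen=True)
class BarycentricSample:
    t: float
    b_left: float        # left eye, mirrored onto the nasal(0)->temporal(1) axis
    b_right: float
    misalignment: float  # b_left - b_right, in [-1, 1]


class AlignmentResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    drift_total: float            # barycentric units over the exercise (slope x duration)
    mean_abs_misalignment: float
    flag: Literal["normal", "abnormal", "indeterminate"]


def barycentric_coordinate(frame: LandmarkFrame, eye: Literal["L", "R"]) -> float:
    """Iris position within the fissure, 0 = nasal canthus, 1 = temporal.

    Signed differences make the value invariant to translation and uniform
    scaling of all coordinates; the result is clamped to [0, 1]. Falls back
    to the iris lower-boundary point when the iris center is not provided.
    """
    inner = frame.points.get(f"eye_inner_{eye}")
    outer = frame.points.get(f"eye_outer_{eye}")
    iris = frame.points.get(f"iris_center_{eye}") or frame.points.get(f"iris_bottom_{eye}")
    if inner is None or outer is None or iris is None:
        raise InsufficientDataError(f"missing canthus/iris landmarks for eye {eye}")
    den = outer[0] - inner[0]
    if abs(den) < MIN_EYE_WIDTH_PX:
        raise LowResolutionError(
            f"eye {eye} width {abs(den):.1f} px below {MIN_EYE_WIDTH_PX} px; iris unresolvable"
        )
    b = (iris[0] - inner[0]) / den
    return float(np.clip(b, 0.0, 1.0))


def misalignment_series(series: LandmarkSeries) -> list[BarycentricSample]:
    """Per-frame inter-eye barycentric difference on a common axis.

    The left eye is mirrored (b -> 1 - b) so both eyes share one axis in
    image space; conjugate gaze then cancels in the difference.
    """
    out: list[BarycentricSample] = []
    usable = {"L": 0, "R": 0}
    for f in series.frames:
        bs = {}
        for eye in ("L", "R"):
            try:
                bs[eye] = barycentric_coordinate(f, eye)  # type: ignore[arg-type]
                usable[eye] += 1
            except (InsufficientDataError, LowResolutionError):
                pass
        if len(bs) == 2:
            bl = 1.0 - bs["L"]
            out.append(BarycentricSample(t=f.t, b_left=bl, b_right=bs["R"],
                                         misalignment=bl - bs["R"]))
    if not out:
        for eye in ("L", "R"):
            if usable[eye] == 0:
                raise InsufficientDataError(f"eye {eye} unusable in every frame")
        raise InsufficientDataError("no frame with both eyes usable")
    return out


def _vertical_dominant(series: LandmarkSeries, horizontal_excursion: float) -> bool:
    """Large vertical iris excursion with no horizontal signal -> indeterminate."""
    vex = []
    for eye in ("L", "R"):
        t, _, y, _ = series.coords(f"iris_center_{eye}")
        _, xi, _, _ = series.coords(f"eye_inner_{eye}")
        _, xo, _, _ = series.coords(f"eye_outer_{eye}")
        if len(y) and len(xi) and len(xo):
            width = float(np.median(np.abs(xo[: len(xi)] - xi[: len(xo)])))
            if width > 0:
                vex.append(float(np.ptp(y)) / width)
    if not vex:
        return False
    return max(vex) > 0.5 and horizontal_excursion < 0.05


def alignment_drift(
    samples: Sequence[BarycentricSample],
    floor: float = 0.05,
    series: LandmarkSeries | None = None,
) -> AlignmentResult:
    """Least-squares drift of the misalignment over the exercise.

    ``drift_total`` = OLS slope x duration. |drift_total| below ``floor`` is
    flagged indeterminate (below instrument resolution); an abnormal flag is
    assigned by the normative module, so above-floor results start "normal".
    """
    t = np.array([s.t for s in samples])
    m = np.array([s.misalignment for s in samples])
    if len(t) < 3 or t[-1] - t[0] < 2.0:
        raise InsufficientDataError("alignment drift needs at least 2 s of samples")
    slope, _, _ = fit_linear_drift(t, m)
    duration = float(t[-1] - t[0])
    drift_total = slope * duration
    flag = "indeterminate" if abs(drift_total) < floor else "normal"
    if series is not None and _vertical_dominant(series, float(np.ptp(m))):
        flag = "indeterminate"
    return AlignmentResult(
        drift_total=float(drift_total),
        mean_abs_misalignment=float(np.mean(np.abs(m))),
        flag=flag,
    )


def _norm_token(text: str) -> str:
    return "".join(ch for ch in text.lower() if ch.isalnum() or ch == " ").strip()


def detect_diplopia_report(
    transcript: TranscriptWords,
    keywords: Iterable[str] = DEFAULT_DIPLOPIA_KEYWORDS,
) -> list[float]:
    """Start times of spoken double-vision reports.

    Case-insensitive; multi-word keywords match over adjacent words. Returns
    an empty list when nothing matches.
    """
    phrases = [tuple(_norm_token(k).split()) for k in keywords]
    tokens = [_norm_token(w.text) for w in transcript.words]
    hits: list[float] = []
    for i in range(len(tokens)):
        for phrase in phrases:
            j = i + len(phrase)
            if j <= len(tokens) and tuple(tokens[i:j]) == phrase:
                hits.append(transcript.words[i].start)
                break
    return sorted(set(hits))
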