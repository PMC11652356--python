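"""Core domain types and file readers for exam recordings.

A recording of one MG-CE exercise arrives as a time-stamped series of named
2D anatomical landmarks (pixels, video convention: origin top-left, y grows
downward) plus, for the vocal exercises, a word-level transcript with start
and end times in seconds, the shape produced by commercial ASR tools.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import DataValidationError, ParseError

Exercise = Literal["ptosis", "diplopia", "arm", "sit_to_stand", "count50", "single_breath"]

EXERCISES: tuple[str, ...] = ("ptosis", "diplopia", "arm", "sit_to_stand", "count50", "single_breath")

#: Fixed landmark name registry. Detector adapters must map their own output
#: onto these names; the core never depends on a specific landmark model.
LANDMARK_REGISTRY: frozenset[str] = frozenset(
    [
        *(f"{base}_{side}" for side in ("L", "R") for base in (
            "eye_inner", "eye_outer", "lid_upper", "lid_lower",
            "iris_center", "iris_bottom",
            "shoulder", "elbow", "wrist", "hip",
        )),
        "chin", "head_top", "lip_upper", "lip_lower", "mouth_left", "mouth_right",
    ]
)


class LandmarkFrame(BaseModel):
    """Named 2D points (px) with detection confidences at one video frame."""

    model_config = ConfigDict(frozen=True)

    t: float = Field(ge=0.0)
    points: Mapping[str, tuple[float, float, float]]  # name -> (x, y, confidence)

    @field_validator("points")
    @classmethod
    def _check_points(cls, points):
        for name, (x, y, c) in points.items():
            if name not in LANDMARK_REGISTRY:
                raise ValueError(f"unknown landmark name {name!r}")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinates for {name!r}")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"confidence {c} for {name!r} outside [0, 1]")
        return dict(points)


class LandmarkSeries(BaseModel):
    """One exercise recording: ordered frames at a nominal frame rate."""

    model_config = ConfigDict(frozen=True)

    frames: tuple[LandmarkFrame, ...]
    fps: float = Field(gt=0.0)
    exercise: Exercise

    @model_validator(mode="after")
    def _check_monotone(self):
        ts = [f.t for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame times must be strictly increasing")
        return self

    @property
    def duration(self) -> float:
        if not self.frames:
            return 0.0
        return self.frames[-1].t - self.frames[0].t

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames], dtype=float)

    def landmark_names(self) -> set[str]:
        names: set[str] = set()
        for f in self.frames:
            names.update(f.points)
        return names

    def coords(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(t, x, y, confidence) arrays over the frames that contain ``name``."""
        t, x, y, c = [], [], [], []
        for f in self.frames:
            p = f.points.get(name)
            if p is not None:
                t.append(f.t)
                x.append(p[0])
                y.append(p[1])
                c.append(p[2])
        return (np.array(t), np.array(x), np.array(y), np.array(c))

    def coverage(self, name: str, min_confidence: float = 0.0) -> float:
        """Fraction of frames where ``name`` is present with confidence >= threshold."""
        if not self.frames:
            return 0.0
        n = sum(1 for f in self.frames if name in f.points and f.points[name][2] >= min_confidence)
        return n / len(self.frames)

    @classmethod
    def from_arrays(
        cls,
        t: np.ndarray,
        points: Mapping[str, tuple[np.ndarray, np.ndarray]],
        fps: float,
        exercise: str,
        confidence: float | Mapping[str, np.ndarray] = 1.0,
    ) -> "LandmarkSeries":
        """Fast constructor from per-landmark coordinate arrays.

        ``points`` maps landmark name to (x, y) arrays aligned with ``t``;
        NaN coordinates mean "absent in that frame".
        """
        t = np.asarray(t, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataValidationError("frame times must be strictly increasing")
        for name in points:
            if name not in LANDMARK_REGISTRY:
                raise DataValidationError(f"unknown landmark name {name!r}")
        frames = []
        for i, ti in enumerate(t):
            pts = {}
            for name, (x, y) in points.items():
                xi, yi = float(x[i]), float(y[i])
                if math.isnan(xi) or math.isnan(yi):
                    continue
                if isinstance(confidence, Mapping):
                    ci = float(confidence[name][i])
                else:
                    ci = float(confidence)
                pts[name] = (xi, yi, ci)
            frames.append(LandmarkFrame.model_construct(t=float(ti), points=pts))
        return cls.model_construct(frames=tuple(frames), fps=float(fps), exercise=exercise)


class Word(BaseModel):
    """One transcript token with ASR timestamps in seconds."""

    model_config = ConfigDict(frozen=True)

    text: str
    start: float
    end: float

    @model_validator(mode="after")
    def _check_span(self):
        if self.start > self.end:
            raise ValueError(f"word {self.text!r}: start {self.start} > end {self.end}")
        return self


class TranscriptWords(BaseModel):
    """Ordered word-level transcript of one vocal exercise."""

    model_config = ConfigDict(frozen=True)

    words: tuple[Word, ...]

    @model_validator(mode="after")
    def _check_order(self):
        starts = [w.start for w in self.words]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("words must be ordered by start time")
        return self


class Participant(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    age_years: float = Field(ge=0.0, allow_inf_nan=False)
    group: Literal["patient", "control"]


# ---------------------------------------------------------------------------
# readers / writers


def _series_from_long(df: pd.DataFrame, fps: float | None, exercise: str) -> LandmarkSeries:
    required = ["t", "name", "x", "y", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"CSV is missing columns {missing}; expected header {','.join(required)}")
    bad = df.index[~df["confidence"].between(0.0, 1.0)]
    if len(bad):
        raise DataValidationError(f"confidence outside [0, 1] at line {int(bad[0]) + 2}")
    bad = df.index[~np.isfinite(df["x"]) | ~np.isfinite(df["y"])]
    if len(bad):
        raise DataValidationError(f"non-finite coordinate at line {int(bad[0]) + 2}")

    df = df.sort_values("t", kind="stable")
    frames = []
    for t, grp in df.groupby("t", sort=True):
        pts = {
            str(r["name"]): (float(r["x"]), float(r["y"]), float(r["confidence"]))
            for _, r in grp.iterrows()
        }
        frames.append(LandmarkFrame(t=float(t), points=pts))
    if fps is None:
        ts = np.array([f.t for f in frames])
        if len(ts) < 2:
            raise ParseError("cannot infer fps from fewer than 2 frames; pass fps explicitly")
        fps = float(np.round(1.0 / np.median(np.diff(ts))))
    try:
        return LandmarkSeries(frames=tuple(frames), fps=fps, exercise=exercise)
    except ValueError as e:  # duplicate / non-monotone t
        raise DataValidationError(str(e)) from e


def read_landmark_series(
    path: str | Path,
    dialect: Literal["csv_long", "json", "auto"] = "auto",
    *,
    fps: float | None = None,
    exercise: str | None = None,
) -> LandmarkSeries:
    """Read a landmark series from CSV long format or JSON.

    CSV long format: header ``t,name,x,y,confidence`` (one row per landmark
    per frame); the JSON dialect carries fps and exercise in the file. JSON
    frames are re-sorted ascending by t; missing landmarks are absent keys.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "json" if path.suffix.lower() == ".json" else "csv_long"
    if dialect == "csv_long":
        if exercise is None:
            raise ParseError("CSV dialect carries no exercise field; pass exercise=")
        try:
            df = pd.read_csv(path)
        except Exception as e:
            raise ParseError(f"malformed CSV {path}: {e}") from e
        return _series_from_long(df, fps, exercise)
    if dialect == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ParseError(f"malformed JSON {path} at line {e.lineno}") from e
        try:
            frames = sorted(obj["frames"], key=lambda fr: fr["t"])
            built = [
                LandmarkFrame(
                    t=fr["t"],
                    points={k: tuple(v) for k, v in fr.get("points", {}).items()},
                )
                for fr in frames
            ]
            return LandmarkSeries(
                frames=tuple(built),
                fps=float(obj["fps"]),
                exercise=str(exercise or obj["exercise"]),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise DataValidationError(f"invalid landmark JSON {path}: {e}") from e
    raise ParseError(f"unknown dialect {dialect!r}")


def write_landmark_series(series: LandmarkSeries, path: str | Path) -> None:
    obj = {
        "fps": series.fps,
        "exercise": series.exercise,
        "frames": [
            {"t": f.t, "points": {k: list(v) for k, v in f.points.items()}}
            for f in series.frames
        ],
    }
    Path(path).write_text(json.dumps(obj, sort_keys=True))


def read_transcript(path: str | Path, units: Literal["s", "ms", "auto"] = "auto") -> TranscriptWords:
    """Read ``{"words": [{"text", "start", "end"}, ...]}``.

    ASR tools commonly emit integer milliseconds; ``units="auto"`` converts
    when all timestamps are integral and the maximum end exceeds 1000.
    """
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed JSON {path} at line {e.lineno}") from e
    try:
        raw = [(str(w["text"]), float(w["start"]), float(w["end"])) for w in obj["words"]]
    except (KeyError, TypeError, ValueError) as e:
        raise DataValidationError(f"invalid transcript JSON {path}: {e}") from e
    if raw and units == "auto":
        integral = all(s == int(s) and e == int(e) for _, s, e in raw)
        units = "ms" if integral and max(e for _, _, e in raw) >= 1000 else "s"
    scale = 1e-3 if units == "ms" else 1.0
    words = sorted(
        (Word(text=t, start=s * scale, end=e * scale) for t, s, e in raw),
        key=lambda w: w.start,
    )
    return TranscriptWords(words=tuple(words))


def write_transcript(transcript: TranscriptWords, path: str | Path) -> None:
    obj = {"words": [{"text": w.text, "start": w.start, "end": w.end} for w in transcript.words]}
    Path(path).write_text(json.dumps(obj))
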