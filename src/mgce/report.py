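"""Per-exercise metric aggregation, session orchestration and report I/O.

`run_session` chains QC -> metrics -> normative flags for every exercise a
caller provides input for; exercises failing QC appear in the report with
the failure reasons and no flags. Reports serialize deterministically
(sorted keys), so identical inputs and configuration yield byte-identical
JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__ as _version
from .alignment import alignment_drift, detect_diplopia_report, misalignment_series
from .config import config_hash, load_config
from .data import Exercise, LandmarkSeries, Participant, TranscriptWords
from .errors import DataValidationError, InsufficientDataError, MgceError, SegmentNotFoundError
from .limb import analyze_arm, detect_ascend
from .mouth import mean_abs_acceleration, mouth_motion_series
from .norms import (
    DIRECTIONS,
    NormativeStats,
    Stratum,
    apply_threshold,
    paper_implied_norms,
    stratum_of,
)
from .ptosis import analyze_ptosis
from .qc import QCReport, run_qc
from .speech import (
    count_rate_metrics,
    locate_count_segment,
    parse_number_words,
    single_breath_metrics,
)

Flag = Literal["normal", "abnormal", "indeterminate"]


class ExerciseMetrics(BaseModel):
    """Numeric outputs of one exercise, with units, QC status and flags."""

    model_config = ConfigDict(frozen=True)

    exercise: Exercise
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    labels: dict[str, str] = {}
    qc: Optional[QCReport] = None
    flags: dict[str, Flag] = {}

    @model_validator(mode="after")
    def _flags_exist(self):
        unknown = set(self.flags) - set(self.values)
        if unknown:
            raise ValueError(f"flags for unknown metrics: {sorted(unknown)}")
        return self


def write_metrics_report(
    metrics: Sequence[ExerciseMetrics],
    path: str | Path,
    format: Literal["json", "csv"] = "json",
) -> None:
    """Write metrics; a round-trip read reproduces all numeric values exactly."""
    if not metrics:
        raise DataValidationError("metrics sequence is empty")
    path = Path(path)
    if format == "json":
        obj = [m.model_dump() for m in metrics]
        path.write_text(json.dumps(obj, sort_keys=True, indent=1))
    elif format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["exercise", "metric", "value", "unit", "flag"])
            for m in metrics:
                for name in sorted(m.values):
                    w.writerow([
                        m.exercise, name, repr(m.values[name]),
                        m.units.get(name, ""), m.flags.get(name, ""),
                    ])
    else:
        raise DataValidationError(f"unknown report format {format!r}")


def read_metrics_report(path: str | Path, format: Literal["json", "csv"] = "json") -> list[ExerciseMetrics]:
    path = Path(path)
    if format == "json":
        return [ExerciseMetrics(**m) for m in json.loads(path.read_text())]
    if format == "csv":
        grouped: dict[str, dict[str, dict]] = {}
        with path.open() as fh:
            for row in csv.DictReader(fh):
                g = grouped.setdefault(row["exercise"], {"values": {}, "units": {}, "flags": {}})
                g["values"][row["metric"]] = float(row["value"])
                if row["unit"]:
                    g["units"][row["metric"]] = row["unit"]
                if row["flag"]:
                    g["flags"][row["metric"]] = row["flag"]
        return [
            ExerciseMetrics(exercise=ex, values=g["values"], units=g["units"], flags=g["flags"])
            for ex, g in grouped.items()
        ]
    raise DataValidationError(f"unknown report format {format!r}")


class SessionReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant: Optional[Participant] = None
    exercises: tuple[ExerciseMetrics, ...]
    norms_used: dict[str, dict[str, NormativeStats]] = {}
    tool_version: str = _version
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=1)


def _flag(
    metric_key: str,
    value: float,
    norms: Mapping[str, Mapping[str, NormativeStats]],
    stratum: Stratum,
) -> Flag:
    strata = norms.get(metric_key)
    if not strata or stratum not in strata:
        return "indeterminate"
    return apply_threshold(value, strata[stratum])


def _analyze_one(
    exercise: str,
    series: Optional[LandmarkSeries],
    transcript: Optional[TranscriptWords],
    cfg: dict,
    norms: Mapping[str, Mapping[str, NormativeStats]],
    stratum: Stratum,
) -> ExerciseMetrics:
    qc = run_qc(series, cfg) if series is not None else QCReport.ok(exercise)
    if not qc.passed:
        return ExerciseMetrics(exercise=exercise, qc=qc)

    values: dict[str, float] = {}
    units: dict[str, str] = {}
    labels: dict[str, str] = {}
    flags: dict[str, Flag] = {}

    if exercise == "ptosis":
        res = analyze_ptosis(series, cfg)
        for side, eye in (("left", res.left), ("right", res.right)):
            if eye is None:
                continue
            values[f"retained_pct_{side}"] = eye.retained_pct
            units[f"retained_pct_{side}"] = "%"
            values[f"drift_slope_{side}"] = eye.drift_slope
            units[f"drift_slope_{side}"] = "px/s"
            labels[f"pattern_{side}"] = eye.pattern
            flags[f"retained_pct_{side}"] = _flag("ptosis.retained_pct", eye.retained_pct, norms, stratum)
        labels["head_tilt"] = {True: "detected", False: "absent", None: "indeterminate"}[res.head_tilt_flag]
    elif exercise == "diplopia":
        samples = misalignment_series(series)
        res = alignment_drift(samples, floor=cfg["alignment.floor"], series=series)
        values["drift_total"] = res.drift_total
        units["drift_total"] = "barycentric"
        values["mean_abs_misalignment"] = res.mean_abs_misalignment
        units["mean_abs_misalignment"] = "barycentric"
        if res.flag == "indeterminate":
            flags["drift_total"] = "indeterminate"
        else:
            flags["drift_total"] = _flag("alignment.drift_total", abs(res.drift_total), norms, stratum)
        if transcript is not None:
            reports = detect_diplopia_report(transcript, keywords=cfg["alignment.keywords"])
            values["diplopia_reports"] = float(len(reports))
            units["diplopia_reports"] = "count"
            if reports:
                values["first_diplopia_report_s"] = reports[0]
                units["first_diplopia_report_s"] = "s"
    elif exercise == "arm":
        thr = norms.get("arm.drift_total", {}).get(stratum)
        res = analyze_arm(series, cfg, abnormal_threshold=thr.threshold if thr else None)
        for side, arm in (("left", res.left), ("right", res.right)):
            values[f"hold_time_{side}"] = arm.hold_time
            units[f"hold_time_{side}"] = "s"
            values[f"drift_total_{side}"] = arm.drift_total
            units[f"drift_total_{side}"] = "rad"
            values[f"drift_slope_{side}"] = arm.drift_slope
            units[f"drift_slope_{side}"] = "rad/s"
            labels[f"pattern_{side}"] = arm.pattern
            if res.seated_stable:
                flags[f"drift_total_{side}"] = _flag("arm.drift_total", arm.drift_total, norms, stratum)
            else:
                flags[f"drift_total_{side}"] = "indeterminate"
    elif exercise == "sit_to_stand":
        res = detect_ascend(
            series, velocity_frac=cfg["sts.velocity_frac"],
            min_rise_frac=cfg["sts.min_rise_frac"], window_s=cfg["sts.window_s"],
        )
        values["able_to_stand"] = float(res.able_to_stand)
        units["able_to_stand"] = "bool"
        labels["partial_view"] = "yes" if res.partial_view else "no"
        if res.ascend_time is not None:
            values["ascend_time"] = res.ascend_time
            units["ascend_time"] = "s"
            flags["ascend_time"] = _flag("sts.ascend_time", res.ascend_time, norms, stratum)
    elif exercise == "count50":
        if transcript is None:
            raise InsufficientDataError("count50 requires a transcript")
        tokens = parse_number_words(transcript)
        seg = locate_count_segment(
            tokens, target=cfg["speech.target"], max_skips=cfg["speech.max_skips"],
            min_run=cfg["speech.min_run"], pause_gap_s=cfg["speech.pause_gap_s"],
        )
        mean_iv, cv_iv = count_rate_metrics(seg)
        values.update(elapsed=seg.elapsed, mean_interval=mean_iv, cv_interval=cv_iv,
                      max_value=float(seg.max_value))
        units.update(elapsed="s", mean_interval="s", cv_interval="", max_value="count")
        if series is not None:
            ms = mouth_motion_series(series, normalizer=cfg["mouth.normalizer"])
            t_lo = max(seg.tokens[0].start, ms.samples[0].t)
            t_hi = min(seg.tokens[-1].end, ms.samples[-1].t)
            acc = mean_abs_acceleration(ms.samples, (t_lo, t_hi), smooth_window_s=cfg["mouth.window_s"])
            values["lip_accel"] = acc
            units["lip_accel"] = "1/s^2"
            flags["lip_accel"] = _flag("mouth.mean_abs_accel", acc, norms, stratum)
    elif exercise == "single_breath":
        if transcript is None:
            raise InsufficientDataError("single_breath requires a transcript")
        tokens = parse_number_words(transcript)
        seg = locate_count_segment(
            tokens, target=cfg["speech.target"], max_skips=cfg["speech.max_skips"],
            min_run=cfg["speech.min_run"], pause_gap_s=cfg["speech.pause_gap_s"],
        )
        count, tspan, pauses = single_breath_metrics(seg.tokens, pause_gap_s=cfg["speech.pause_gap_s"])
        values.update(count_reached=float(count), counting_time=tspan, breath_pauses=float(pauses),
                      total_elapsed=seg.elapsed)
        units.update(count_reached="count", counting_time="s", breath_pauses="count", total_elapsed="s")
    else:
        raise DataValidationError(f"unknown exercise {exercise!r}")

    return ExerciseMetrics(exercise=exercise, values=values, units=units,
                           labels=labels, qc=qc, flags=flags)


def run_session(
    inputs: Mapping[str, Mapping[str, object]],
    cfg: dict | None = None,
    participant: Participant | None = None,
    norms: Mapping[str, Mapping[str, NormativeStats]] | None = None,
) -> SessionReport:
    """Analyze one exam session.

    ``inputs`` maps exercise name to {"landmarks": LandmarkSeries, and/or
    "transcript": TranscriptWords}. Exercises failing QC are reported with
    their failure reasons and no flags. Flags use the participant's age
    stratum (under_70 when no participant metadata is given).
    """
    cfg = cfg if cfg is not None else load_config()
    norms = norms if norms is not None else paper_implied_norms()
    if not inputs:
        raise DataValidationError("at least one exercise input is required")
    stratum = stratum_of(participant.age_years, cfg["normative.age_cut"]) if participant else "under_70"
    blocks = []
    for exercise in sorted(inputs):
        payload = inputs[exercise]
        blocks.append(
            _analyze_one(
                exercise,
                payload.get("landmarks"),
                payload.get("transcript"),
                cfg, norms, stratum,
            )
        )
    return SessionReport(
        participant=participant,
        exercises=tuple(blocks),
        norms_used={m: dict(s) for m, s in norms.items()},
        config_hash=config_hash(cfg),
    )
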