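"""Control-derived normative thresholds and abnormality flagging.

Every metric is flagged against the control mean +/- one sample standard
deviation, in the direction that is abnormal for that metric, stratified by
age at 70 years (strictly greater than 70 enters the older stratum). Values
exactly on the threshold are normal. Under a normal control model the
expected abnormal rate among fresh controls is Phi(-1) ~= 15.9%.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DataValidationError, InsufficientDataError

Direction = Literal["lower_is_abnormal", "higher_is_abnormal"]
Stratum = Literal["under_70", "over_70"]

#: Which side of the control distribution is abnormal, per summary metric.
DIRECTIONS: dict[str, Direction] = {
    "ptosis.retained_pct": "lower_is_abnormal",
    "alignment.drift_total": "higher_is_abnormal",
    "arm.drift_total": "lower_is_abnormal",
    "sts.ascend_time": "higher_is_abnormal",
    "mouth.mean_abs_accel": "lower_is_abnormal",
}


class NormativeStats(BaseModel):
    model_config = ConfigDict(frozen=True)

    metric_name: str
    stratum: Stratum
    mean: float
    sd: float
    direction: Direction
    threshold: float
    n: int = 0
    provenance: str = "site-computed"

    @model_validator(mode="after")
    def _consistent(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        expected = self.mean - self.sd if self.direction == "lower_is_abnormal" else self.mean + self.sd
        if abs(self.threshold - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("threshold inconsistent with mean, sd and direction")
        return self


def stratum_of(age_years: float, age_cut: float = 70.0) -> Stratum:
    """Age stratum; strictly older than the cut enters the older stratum."""
    return "over_70" if age_years > age_cut else "under_70"


def compute_normative(
    control_values: Sequence[tuple[float, float]],
    metric_name: str,
    direction: Direction,
    age_cut: float = 70.0,
) -> dict[Stratum, NormativeStats]:
    """Per-stratum mean, sample SD (n-1) and threshold from control (value, age) pairs.

    A stratum with fewer than 2 controls is absent from the result.
    """
    if not control_values:
        raise InsufficientDataError("no control values")
    out: dict[Stratum, NormativeStats] = {}
    for stratum in ("under_70", "over_70"):
        vals = np.array([v for v, age in control_values if stratum_of(age, age_cut) == stratum])
        if len(vals) < 2:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        thr = mean - sd if direction == "lower_is_abnormal" else mean + sd
        out[stratum] = NormativeStats(
            metric_name=metric_name, stratum=stratum, mean=mean, sd=sd,
            direction=direction, threshold=thr, n=len(vals),
        )
    return out


def apply_threshold(value: float, stats: NormativeStats) -> Literal["normal", "abnormal"]:
    """Abnormal iff strictly beyond the threshold in the abnormal direction."""
    if stats.direction == "lower_is_abnormal":
        return "abnormal" if value < stats.threshold else "normal"
    return "abnormal" if value > stats.threshold else "normal"


def _implied(metric: str, stratum: Stratum, mean: float, sd: float, direction: Direction) -> NormativeStats:
    thr = mean - sd if direction == "lower_is_abnormal" else mean + sd
    return NormativeStats(metric_name=metric, stratum=stratum, mean=mean, sd=sd,
                          direction=direction, threshold=thr, n=15, provenance="paper-implied")


def paper_implied_norms() -> dict[str, dict[Stratum, NormativeStats]]:
    """Default norms reconstructed from published control summaries.

    Arm drift: control means -0.05 (under 70) and -0.15 rad (over 70) with
    thresholds -0.12 / -0.24, implying SDs 0.07 / 0.09. Ptosis: controls
    retain >= 96% of maximum aperture (filtered variation at most 4%),
    shipped as mean 100, SD 4. SDs are implied, not printed; treat as
    provisional until site-computed norms replace them.
    """
    return {
        "arm.drift_total": {
            "under_70": _implied("arm.drift_total", "under_70", -0.05, 0.07, "lower_is_abnormal"),
            "over_70": _implied("arm.drift_total", "over_70", -0.15, 0.09, "lower_is_abnormal"),
        },
        "ptosis.retained_pct": {
            "under_70": _implied("ptosis.retained_pct", "under_70", 100.0, 4.0, "lower_is_abnormal"),
        },
    }


# --- JSON serialization so a site can ship frozen control norms -------------

def write_norms(norms: dict[str, dict[Stratum, NormativeStats]], path: str | Path) -> None:
    obj = {
        metric: {stratum: stats.model_dump() for stratum, stats in strata.items()}
        for metric, strata in norms.items()
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_norms(path: str | Path) -> dict[str, dict[Stratum, NormativeStats]]:
    obj = json.loads(Path(path).read_text())
    try:
        return {
            metric: {stratum: NormativeStats(**stats) for stratum, stats in strata.items()}
            for metric, strata in obj.items()
        }
    except (TypeError, ValueError) as e:
        raise DataValidationError(f"invalid norms file {path}: {e}") from e
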