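"""Synthetic exam sessions with known ground truth.

Every metric in the package is exercised against landmark series and
transcripts generated from a canonical face/body template: lid apertures
with linear droop or square-wave "struggle" instability, iris drift or
conjugate gaze wander, arm-angle decay with optional abrupt drop, a logistic
sit-to-stand hip rise, counting transcripts with controllable rate, injected
misrecognitions and breath pauses, and sinusoidal lip motion. Measurement
noise is i.i.d. Gaussian pixel jitter per landmark coordinate; the default
sd of 0.25 px is calibrated so control lid recordings show at most ~4%
filtered aperture variation at a 20 px aperture, the bound controls exhibit
in practice. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .data import LandmarkSeries, TranscriptWords, Word
from .limb import LOGISTIC_ASCEND_SPAN

# canonical template, pixels (origin top-left, y downward)
_EYE_CENTER = {"L": (340.0, 220.0), "R": (260.0, 220.0)}
_EYE_HALF_WIDTH = 20.0  # canthus to eye center
_CHIN = (300.0, 300.0)
_HEAD_TOP = (300.0, 120.0)
_SHOULDER = {"L": (360.0, 380.0), "R": (240.0, 380.0)}
_HIP = {"L": (330.0, 560.0), "R": (270.0, 560.0)}
_ARM_LENGTH = 150.0
_MOUTH_Y = 280.0
_MOUTH_HALF_WIDTH = 20.0
_LIP_UPPER_Y = 272.0
_LIP_LOWER_Y = 288.0


class PtosisSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    true_retained_pct: float = Field(default=100.0, gt=0.0, le=100.0)
    pattern: Literal["stable", "linear", "unstable"] = "stable"
    noise_sd_px: float = Field(default=0.25, ge=0.0)
    duration_s: float = Field(default=60.0, gt=0.0)
    base_aperture_px: float = Field(default=20.0, gt=0.0)
    head_tilt_frac: float = 0.0  # >0: chin-to-crown extent shrinks by this fraction

    @model_validator(mode="after")
    def _pattern_consistent(self):
        if self.pattern == "stable" and self.true_retained_pct < 100.0:
            raise ValueError("stable pattern requires true_retained_pct = 100")
        return self


class AlignmentSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    true_drift: float = Field(default=0.0, ge=-1.0, le=1.0)
    conjugate_gaze: bool = False
    gaze_wander_px: float = 8.0  # conjugate co-movement amplitude
    noise_sd_px: float = Field(default=0.25, ge=0.0)
    duration_s: float = Field(default=60.0, gt=0.0)


class ArmSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    true_slope_rad_s: float = 0.0  # negative = downward drift
    drop_time_s: Optional[float] = None  # abrupt drop, seconds from start
    start_angle_deg: float = 80.0
    drop_angle_deg: float = 20.0
    noise_sd_px: float = Field(default=0.25, ge=0.0)
    duration_s: float = Field(default=150.0, gt=0.0)


class StsSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    true_ascend_s: float = Field(default=1.2, gt=0.0)
    able: bool = True
    include_head: bool = True
    noise_sd_px: float = Field(default=0.0, ge=0.0)
    duration_s: float = Field(default=10.0, gt=0.0)


class SpeechSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    rate_s: float = Field(default=0.8, gt=0.0)  # onset-to-onset interval
    max_count: int = Field(default=50, ge=1, le=50)
    word_s: float = Field(default=0.3, gt=0.0)
    skip_errors: int = Field(default=0, ge=0)       # values silently missing
    misrecognitions: int = Field(default=0, ge=0)   # values replaced by junk words
    pause_after: Optional[int] = None               # breath pause after this value
    pause_len_s: float = Field(default=1.8, gt=0.0)


class MouthSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    amplitude: float = Field(default=0.05, gt=0.0)  # normalized distance units
    freq_hz: float = Field(default=2.0, gt=0.0)
    noise_sd_px: float = Field(default=0.0, ge=0.0)
    duration_s: float = Field(default=40.0, gt=0.0)


class SyntheticSpec(BaseModel):
    """Ground truth for one synthetic exam session."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    fps: float = Field(default=25.0, gt=0.0)
    camera_scale: float = Field(default=1.0, gt=0.0)
    ptosis: PtosisSpec = PtosisSpec()
    alignment: AlignmentSpec = AlignmentSpec()
    arm: ArmSpec = ArmSpec()
    sts: StsSpec = StsSpec()
    speech: SpeechSpec = SpeechSpec()
    mouth: MouthSpec = MouthSpec()


def _times(duration_s: float, fps: float) -> np.ndarray:
    n = int(round(duration_s * fps))
    return np.arange(n) / fps


def _assemble(
    t: np.ndarray,
    points: dict[str, tuple[np.ndarray, np.ndarray]],
    spec: SyntheticSpec,
    exercise: str,
    noise_sd_px: float,
    rng: np.random.Generator,
) -> LandmarkSeries:
    s = spec.camera_scale
    noisy = {}
    for name, (x, y) in points.items():
        x = np.asarray(x, dtype=float) * s
        y = np.asarray(y, dtype=float) * s
        if noise_sd_px > 0:
            x = x + rng.normal(0.0, noise_sd_px, size=len(t))
            y = y + rng.normal(0.0, noise_sd_px, size=len(t))
        noisy[name] = (x, y)
    return LandmarkSeries.from_arrays(t, noisy, fps=spec.fps, exercise=exercise)


def _const(t: np.ndarray, xy: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    return np.full_like(t, xy[0]), np.full_like(t, xy[1])


def _aperture_trajectory(t: np.ndarray, p: PtosisSpec) -> np.ndarray:
    a0 = p.base_aperture_px
    r = p.true_retained_pct / 100.0
    T = t[-1] if len(t) else 0.0
    if p.pattern == "stable" or r >= 1.0:
        return np.full_like(t, a0)
    if p.pattern == "linear":
        # plateau at max, linear droop, then a floor plateau: the floor holds
        # the true robust minimum and the opening plateau the true maximum
        t_top, t_floor = 0.08 * T, 0.80 * T
        a = np.full_like(t, a0)
        ramp = (t >= t_top) & (t < t_floor)
        a[ramp] = a0 + (r * a0 - a0) * (t[ramp] - t_top) / (t_floor - t_top)
        a[t >= t_floor] = r * a0
        return a
    # unstable: bounded open/shut struggle, square wave, 4 s period
    phase = np.floor(t / 2.0).astype(int) % 2
    return np.where(phase == 0, a0, r * a0)


def gen_ptosis_session(spec: SyntheticSpec) -> tuple[LandmarkSeries, SyntheticSpec]:
    """Sustained-upgaze session whose filtered aperture realizes the spec."""
    p = spec.ptosis
    rng = np.random.default_rng(spec.seed)
    t = _times(p.duration_s, spec.fps)
    ap = _aperture_trajectory(t, p)

    points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for side in ("L", "R"):
        cx, cy = _EYE_CENTER[side]
        sgn = 1.0 if side == "L" else -1.0
        points[f"eye_inner_{side}"] = _const(t, (cx - sgn * _EYE_HALF_WIDTH, cy))
        points[f"eye_outer_{side}"] = _const(t, (cx + sgn * _EYE_HALF_WIDTH, cy))
        points[f"lid_upper_{side}"] = (np.full_like(t, cx), cy - ap / 2.0)
        points[f"lid_lower_{side}"] = (np.full_like(t, cx), cy + ap / 2.0)
        points[f"iris_bottom_{side}"] = (np.full_like(t, cx), cy - ap / 2.0 + 0.75 * ap)
        points[f"iris_center_{side}"] = _const(t, (cx, cy))
    extent = _CHIN[1] - _HEAD_TOP[1]
    shrink = 1.0 - spec.ptosis.head_tilt_frac * (t / t[-1] if len(t) else 0.0)
    points["chin"] = _const(t, _CHIN)
    points["head_top"] = (np.full_like(t, _HEAD_TOP[0]), _CHIN[1] - extent * shrink)
    series = _assemble(t, points, spec, "ptosis", p.noise_sd_px, rng)
    return series, spec


def gen_alignment_session(spec: SyntheticSpec) -> tuple[LandmarkSeries, SyntheticSpec]:
    """Eccentric-gaze session with a known misalignment drift.

    With ``conjugate_gaze`` the irises co-move in image space (yoked gaze
    wander) and the true drift is zero; otherwise the left iris drifts
    temporally so the inter-eye barycentric difference ramps 0 -> true_drift.
    """
    a = spec.alignment
    rng = np.random.default_rng(spec.seed + 1)
    t = _times(a.duration_s, spec.fps)
    T = t[-1] if len(t) else 1.0
    eye_w = 2.0 * _EYE_HALF_WIDTH

    wander = a.gaze_wander_px * np.sin(2.0 * math.pi * 0.2 * t) if a.conjugate_gaze else 0.0
    g = {"L": np.full_like(t, 0.0), "R": np.full_like(t, 0.0)}
    g["L"] = g["L"] - eye_w * a.true_drift * t / T  # -x on the left eye raises mirrored b
    for side in ("L", "R"):
        g[side] = g[side] + wander

    ap = np.full_like(t, 15.0)
    points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for side in ("L", "R"):
        cx, cy = _EYE_CENTER[side]
        sgn = 1.0 if side == "L" else -1.0
        points[f"eye_inner_{side}"] = _const(t, (cx - sgn * _EYE_HALF_WIDTH, cy))
        points[f"eye_outer_{side}"] = _const(t, (cx + sgn * _EYE_HALF_WIDTH, cy))
        points[f"iris_center_{side}"] = (cx + g[side], np.full_like(t, cy))
        points[f"iris_bottom_{side}"] = (cx + g[side], cy + ap * 0.25)
        points[f"lid_upper_{side}"] = (np.full_like(t, cx), cy - ap / 2.0)
        points[f"lid_lower_{side}"] = (np.full_like(t, cx), cy + ap / 2.0)
    series = _assemble(t, points, spec, "diplopia", a.noise_sd_px, rng)
    return series, spec


def arm_theta_truth(t: np.ndarray, arm: ArmSpec) -> np.ndarray:
    """Ground-truth arm-torso angle trajectory, radians."""
    theta0 = math.radians(arm.start_angle_deg)
    theta = theta0 + arm.true_slope_rad_s * t
    if arm.drop_time_s is not None:
        theta = np.where(t >= arm.drop_time_s, math.radians(arm.drop_angle_deg), theta)
    return np.clip(theta, 0.0, math.pi)


def gen_arm_session(spec: SyntheticSpec) -> tuple[LandmarkSeries, SyntheticSpec]:
    """Seated arm-extension session realizing the spec's decay and drop."""
    arm = spec.arm
    rng = np.random.default_rng(spec.seed + 2)
    t = _times(arm.duration_s, spec.fps)
    theta = arm_theta_truth(t, arm)

    points: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "hip_L": _const(t, _HIP["L"]),
        "hip_R": _const(t, _HIP["R"]),
        "shoulder_L": _const(t, _SHOULDER["L"]),
        "shoulder_R": _const(t, _SHOULDER["R"]),
        "chin": _const(t, _CHIN),
        "head_top": _const(t, _HEAD_TOP),
    }
    # torso axis is vertical (+y down); rotate it by theta outward per side
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        sx, sy = _SHOULDER[side]
        points[f"wrist_{side}"] = (
            sx + sgn * _ARM_LENGTH * np.sin(theta),
            sy + _ARM_LENGTH * np.cos(theta),
        )
    series = _assemble(t, points, spec, "arm", arm.noise_sd_px, rng)
    return series, spec


def gen_sts_session(spec: SyntheticSpec) -> tuple[LandmarkSeries, SyntheticSpec]:
    """Sit-to-stand session: logistic hip rise of known ascending time.

    ``true_ascend_s`` is the span during which upward hip velocity exceeds
    10% of its peak (the ascending-phase definition used by the detector),
    i.e. 7.274 logistic time constants.
    """
    sts = spec.sts
    rng = np.random.default_rng(spec.seed + 3)
    t = _times(sts.duration_s, spec.fps)
    rise_px = 150.0
    if sts.able:
        tau = sts.true_ascend_s / LOGISTIC_ASCEND_SPAN
        lift = rise_px * expit((t - sts.duration_s / 2.0) / tau)
    else:
        lift = np.zeros_like(t)

    hip_y_L = _HIP["L"][1] - lift
    hip_y_R = _HIP["R"][1] - lift
    sh_y_L = _SHOULDER["L"][1] - lift
    sh_y_R = _SHOULDER["R"][1] - lift
    points: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "hip_L": (np.full_like(t, _HIP["L"][0]), hip_y_L),
        "hip_R": (np.full_like(t, _HIP["R"][0]), hip_y_R),
        "shoulder_L": (np.full_like(t, _SHOULDER["L"][0]), sh_y_L),
        "shoulder_R": (np.full_like(t, _SHOULDER["R"][0]), sh_y_R),
    }
    if sts.include_head:
        points["head_top"] = (np.full_like(t, _HEAD_TOP[0]), sh_y_L - 120.0)
    series = _assemble(t, points, spec, "sit_to_stand", sts.noise_sd_px, rng)
    return series, spec


_NUM_WORDS: dict[int, tuple[str, ...]] = {}
for _w, _v in (
    ("one", 1), ("two", 2), ("three", 3), ("four", 4), ("five", 5), ("six", 6),
    ("seven", 7), ("eight", 8), ("nine", 9), ("ten", 10), ("eleven", 11),
    ("twelve", 12), ("thirteen", 13), ("fourteen", 14), ("fifteen", 15),
    ("sixteen", 16), ("seventeen", 17), ("eighteen", 18), ("nineteen", 19),
    ("twenty", 20), ("thirty", 30), ("forty", 40), ("fifty", 50),
):
    _NUM_WORDS[_v] = (_w,)
for _v in range(21, 50):
    if _v not in _NUM_WORDS:
        tens, unit = (_v // 10) * 10, _v % 10
        _NUM_WORDS[_v] = (_NUM_WORDS[tens][0], _NUM_WORDS[unit][0])


def gen_count_transcript(spec: SyntheticSpec) -> tuple[TranscriptWords, SyntheticSpec]:
    """Counting transcript 1..max_count with injected errors and breath pause.

    Compound numbers are emitted as two adjacent words. ``skip_errors``
    values vanish from the transcript; ``misrecognitions`` values are
    replaced by a junk word; a breath pause of ``pause_len_s`` follows the
    value ``pause_after``.
    """
    sp = spec.speech
    rng = np.random.default_rng(spec.seed + 4)
    corruptible = [v for v in range(3, sp.max_count) if v != sp.pause_after]
    n_corrupt = min(sp.skip_errors + sp.misrecognitions, len(corruptible))
    chosen = sorted(rng.choice(corruptible, size=n_corrupt, replace=False).tolist()) if n_corrupt else []
    dropped = set(chosen[: sp.skip_errors])
    junked = set(chosen[sp.skip_errors:])

    words: list[Word] = [Word(text="okay", start=0.2, end=0.5), Word(text="go", start=0.8, end=1.0)]
    onset = 1.5
    for v in range(1, sp.max_count + 1):
        if v in dropped:
            onset += sp.rate_s
            continue
        parts = ("um",) if v in junked else _NUM_WORDS[v]
        span = sp.word_s / len(parts)
        for k, part in enumerate(parts):
            words.append(Word(text=part, start=round(onset + k * span, 4),
                              end=round(onset + (k + 1) * span - 0.01, 4)))
        onset += sp.rate_s
        if sp.pause_after is not None and v == sp.pause_after:
            onset += sp.pause_len_s
    words.append(Word(text="done", start=round(onset + 0.5, 4), end=round(onset + 0.8, 4)))
    return TranscriptWords(words=tuple(words)), spec


def gen_mouth_session(spec: SyntheticSpec) -> tuple[LandmarkSeries, SyntheticSpec]:
    """Counting-mouth session: sinusoidal upper-lip motion of known amplitude.

    The normalized upper-lip position is u(t) = u0 + A sin(2 pi f t), so the
    mean absolute acceleration is A (2 pi f)^2 (2/pi) in closed form.
    """
    m = spec.mouth
    rng = np.random.default_rng(spec.seed + 5)
    t = _times(m.duration_s, spec.fps)
    width = 2.0 * _MOUTH_HALF_WIDTH
    lip_upper_y = _LIP_UPPER_Y + m.amplitude * width * np.sin(2.0 * math.pi * m.freq_hz * t)
    points: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "mouth_left": _const(t, (_EYE_CENTER["R"][0] + 20.0, _MOUTH_Y)),
        "mouth_right": _const(t, (_EYE_CENTER["L"][0] - 20.0, _MOUTH_Y)),
        "lip_upper": (np.full_like(t, 300.0), lip_upper_y),
        "lip_lower": (np.full_like(t, 300.0), np.full_like(t, _LIP_LOWER_Y)),
    }
    series = _assemble(t, points, spec, "count50", m.noise_sd_px, rng)
    return series, spec


def gen_full_session(spec: SyntheticSpec) -> dict[str, object]:
    """All six exercises of one synthetic exam, keyed by exercise name."""
    return {
        "ptosis": gen_ptosis_session(spec)[0],
        "diplopia": gen_alignment_session(spec)[0],
        "arm": gen_arm_session(spec)[0],
        "sit_to_stand": gen_sts_session(spec)[0],
        "count50": {
            "landmarks": gen_mouth_session(spec)[0],
            "transcript": gen_count_transcript(spec)[0],
        },
        "single_breath": {
            "transcript": gen_count_transcript(
                spec.model_copy(update={"speech": spec.speech.model_copy(update={"max_count": 30})})
            )[0]
        },
    }
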