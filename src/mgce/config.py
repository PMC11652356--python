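"""Flat dotted-key configuration with strict unknown-key checking."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

DEFAULTS: dict[str, Any] = {
    # quality control
    "qc.min_aperture_px": 7.0,
    "qc.min_confidence": 0.5,
    "qc.min_coverage": 0.9,
    "qc.supported_fps": [25.0, 30.0],
    # ptosis
    "ptosis.noise_pct": 4.0,
    "ptosis.window_s": 0.5,
    "ptosis.r2_min": 0.6,
    "ptosis.robust_q": 0.05,
    "ptosis.head_tilt_rel_change": 0.15,
    # ocular alignment
    "alignment.floor": 0.05,
    "alignment.keywords": ["double", "two of", "diplopia", "split"],
    # arm endurance
    "arm.start_angle_deg": 70.0,
    "arm.fail_angle_deg": 60.0,
    "arm.cap_s": 120.0,
    "arm.sustain_s": 1.0,
    "arm.abrupt_drop_rad": 0.3,
    # sit-to-stand
    "sts.velocity_frac": 0.10,
    "sts.min_rise_frac": 0.5,
    "sts.window_s": 0.12,
    # speech timing
    "speech.pause_gap_s": 1.0,
    "speech.max_skips": 3,
    "speech.min_run": 5,
    "speech.target": 50,
    # orofacial motion
    "mouth.normalizer": "mouth_width",
    "mouth.window_s": 0.0,
    # normative thresholds
    "normative.age_cut": 70.0,
}


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Defaults, overlaid by an optional YAML file, overlaid by overrides.

    Unknown keys are errors, never warnings.
    """
    cfg = dict(DEFAULTS)
    for source, mapping in (("config file", _read_yaml(path)), ("override", overrides or {})):
        for key, value in mapping.items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown {source} key {key!r}")
            cfg[key] = value
    return cfg


def _read_yaml(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    obj = yaml.safe_load(Path(path).read_text())
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"config file {path} must hold a mapping of dotted keys")
    return obj


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration, for report provenance."""
    canon = json.dumps(dict(sorted(cfg.items())), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def parse_override(item: str) -> tuple[str, Any]:
    """Parse a ``key=value`` command-line override; YAML-typed value."""
    if "=" not in item:
        raise ConfigError(f"override {item!r} is not of the form key=value")
    key, _, raw = item.partition("=")
    return key.strip(), yaml.safe_load(raw)
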