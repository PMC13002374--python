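"""YAML run configuration with explicit units.

Internal canonical units are ms, cm and mV.  Length keys may be given
with a unit suffix (``dx_um``, ``dx_mm``, ``dx_cm``); durations are ms.
Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "parse_config", "DEFAULTS"]

_LENGTH_UNITS = {"um": 1e-4, "mm": 0.1, "cm": 1.0}

DEFAULTS = {
    "kind": "hipsc_suite",            # hipsc_suite | atria_suite
    "nx": 40,
    "ny": 40,
    "dx_cm": 0.025,                   # 250 um
    "base_diffusivity": None,         # cm^2/ms; None -> calibrate
    "target_cv": None,                # cm/s; None -> model default
    "duration_ms": 20_000.0,
    "intensities": [0.5],
    "patch_radius_cm": 0.2,
    "coverage": 0.5,
    "seeds": [1, 2, 3],
    "threshold_mv": 0.0,
    "frame_dt_ms": 2.0,
    "model_id": "paci_hipsc",
}

_KNOWN = set(DEFAULTS) | {"dx_um", "dx_mm", "patch_radius_um", "patch_radius_mm"}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(key) from None

    def to_dict(self) -> dict:
        return dict(self.values)


def _normalize(raw: dict) -> dict:
    cfg = dict(DEFAULTS)
    for key, val in raw.items():
        if key not in _KNOWN:
            raise ValueError(f"unknown configuration key {key!r}")
        base, _, unit = key.rpartition("_")
        if unit in _LENGTH_UNITS and base in ("dx", "patch_radius"):
            cfg[f"{base}_cm"] = float(val) * _LENGTH_UNITS[unit]
        else:
            cfg[key] = val
    if cfg["kind"] not in ("hipsc_suite", "atria_suite"):
        raise ValueError(f"unknown suite kind {cfg['kind']!r}")
    for key in ("nx", "ny"):
        if int(cfg[key]) < 1:
            raise ValueError(f"{key} must be >= 1")
    if cfg["dx_cm"] <= 0:
        raise ValueError("dx must be > 0")
    if cfg["duration_ms"] <= 0:
        raise ValueError("duration_ms must be > 0")
    if not cfg["seeds"]:
        raise ValueError("seeds must be a non-empty list (no silent default)")
    return cfg


def parse_config(path) -> RunConfig:
    """Load, validate and unit-normalize a YAML configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    return RunConfig(_normalize(raw))
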