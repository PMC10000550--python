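"""YAML pipeline configuration: schema, validation, hashing.

One YAML file drives every CLI stage.  All randomness descends from the
single ``seed``; defaults reproduce the reference protocol settings
(416×416 grayscale inputs, Adam, learning rate 0.001, 100 epochs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationParams

__all__ = ["PipelineConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    pass


@dataclass
class SynthSection:
    n: int = 5
    image_size: int = 416
    noise_sd: float = 2.0
    tilt_deg: float = 0.0
    overrides: dict = field(default_factory=dict)


@dataclass
class DetectorSection:
    input_size: int = 416
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.001
    val_fraction: float = 0.2
    augment: bool = True


@dataclass
class MeasureSection:
    canon_tolerance: float = 0.05
    straight_band_mm: float = 1.0
    broken_threshold_mm: float = 5.0
    hump_present: bool | None = None  # None → infer from kyphion presence


@dataclass
class PipelineConfig:
    seed: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    detector: DetectorSection = field(default_factory=DetectorSection)
    measure: MeasureSection = field(default_factory=MeasureSection)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)

    def calibration_params(self) -> CalibrationParams:
        return self.calibration


_SECTIONS = {
    "synth": SynthSection,
    "detector": DetectorSection,
    "measure": MeasureSection,
}


def _build_section(cls, payload: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path_or_dict) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (path) or a dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            payload = yaml.safe_load(fh) or {}
    else:
        payload = dict(path_or_dict or {})
    if not isinstance(payload, dict):
        raise ConfigError(f"config root must be a mapping, got {type(payload).__name__}")
    known = set(_SECTIONS) | {"seed", "calibration"}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    seed = payload.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"seed must be a non-negative integer, got {seed!r}")
    sections = {name: _build_section(cls, payload.get(name, {}) or {}, name) for name, cls in _SECTIONS.items()}
    calib_payload = payload.get("calibration", {}) or {}
    if "optical_center" in calib_payload:
        calib_payload["optical_center"] = tuple(calib_payload["optical_center"])
    try:
        calibration = CalibrationParams(**calib_payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid calibration block: {exc}") from exc
    if sections["synth"].n < 1:
        raise ConfigError("synth.n must be >= 1")
    if sections["detector"].epochs < 1:
        raise ConfigError("detector.epochs must be >= 1")
    return PipelineConfig(seed=seed, calibration=calibration, **sections)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    payload = dataclasses.asdict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
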