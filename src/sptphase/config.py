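"""Run configuration: preprocessing + detection settings from YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import DetectionConfig
from .preprocess import PreprocessConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "detection": dataclasses.asdict(self.detection),
        }


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load a config file with optional ``preprocess``/``detection`` sections."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(
        preprocess=_build(PreprocessConfig, data.get("preprocess", {}) or {},
                          "preprocess"),
        detection=_build(DetectionConfig, data.get("detection", {}) or {},
                         "detection"),
    )
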