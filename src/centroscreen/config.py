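"""Pipeline configuration: one serializable object holding the parameter
blocks of every stage, with the acquisition pixel size (default 0.108 um)
and the run seed. The resolved configuration is written as YAML next to a
run's outputs so every run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_PIXEL_SIZE_UM

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    clustering_score: dict = field(default_factory=dict)
    gating: dict = field(default_factory=dict)
    screen_stats: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def write_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the resolved configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
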