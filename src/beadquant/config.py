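"""Pipeline configuration: one YAML/JSON block per component, plus a seed.

Every command stamps its outputs with the configuration hash and package
version so any result can be traced back to the exact settings that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .detect import DetectionParams
from .errors import ValidationError
from .geometry import ArrayLayout
from .migrate import Registration
from .simulate import OpticsParams, SignalModel

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    layout: ArrayLayout = field(default_factory=ArrayLayout)
    optics: OpticsParams = field(default_factory=OpticsParams)
    signal: SignalModel = field(default_factory=SignalModel)
    detection: DetectionParams | None = None
    registration: Registration = field(default_factory=Registration)
    seed: int = 0
    fill_fraction: float = 1.0

    def __post_init__(self):
        if self.detection is None:
            object.__setattr__(
                self, "detection", DetectionParams(template_radius_px=self.optics.bead_radius_px)
            )
        if not (0.0 <= self.fill_fraction <= 1.0):
            raise ValidationError(f"fill_fraction must lie in [0, 1] (got {self.fill_fraction})")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        blocks = {
            "layout": ArrayLayout,
            "optics": OpticsParams,
            "signal": SignalModel,
            "detection": DetectionParams,
            "registration": Registration,
        }
        for key, val in d.items():
            if key in blocks:
                kwargs[key] = blocks[key](**val) if val is not None else None
            elif key in ("seed", "fill_fraction"):
                kwargs[key] = val
            else:
                raise ValidationError(f"unknown config key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
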