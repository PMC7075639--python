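"""Run configuration: every analysis parameter, resolved and loggable.

All parameters of the pipeline live in one flat mapping that round-trips
losslessly through YAML; every output row carries a hash of the resolved
configuration so reruns are attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import DiffusionParams, PreprocessConfig


@dataclass
class RunConfig:
    """Resolved parameters for a batch analysis run."""

    resolution: float = 6.0                  # pixels per μm
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    actin_blur_sigma: float = 2.0
    gamma_threshold: float = 0.7
    grid_um: float = 5.0
    czl_min_pixels: int = 2
    major_axis_deg: float = 0.0              # rotate angles before the stress estimate
    field_area_mm2: float | None = None      # override; default from image size
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        pp = data.pop("preprocess", {}) or {}
        diff = pp.pop("diffusion", {}) or {}
        preprocess = PreprocessConfig(diffusion=DiffusionParams(**diff), **pp)
        return cls(preprocess=preprocess, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Stable short hash of the resolved parameter values."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
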