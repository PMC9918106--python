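"""Run configuration: YAML-loadable, schema-validated defaults for every
pipeline stage; CLI flags override file values, which override defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import DermspecError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    class_list: list[str] = field(default_factory=lambda: ["BCC", "SCC", "SK"])
    canvas_size: int = 640
    band_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(405.0, 435.0), (525.0, 555.0)]
    )
    pca_k: int = 6
    iou_threshold: float = 0.45
    confidence_threshold: float = 0.25
    precision_convention: str = "exclude-background"
    split_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not self.class_list or len(set(self.class_list)) != len(self.class_list):
            raise DermspecError("class_list: must be non-empty and unique")
        if self.canvas_size < 32:
            raise DermspecError("canvas_size: must be >= 32")
        for lo, hi in self.band_windows:
            if not 380 <= lo <= hi <= 780:
                raise DermspecError(f"band_windows: bad window ({lo}, {hi})")
        if self.pca_k < 1:
            raise DermspecError("pca_k: must be >= 1")
        for name in ("iou_threshold", "confidence_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise DermspecError(f"{name}: must lie in (0, 1)")
        if self.precision_convention not in ("exclude-background", "include-background"):
            raise DermspecError("precision_convention: unknown value")
        if not 0 < self.split_fraction < 1:
            raise DermspecError("split_fraction: must lie in (0, 1)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise DermspecError(f"unknown config fields: {sorted(unknown)}")
        if "band_windows" in payload:
            payload["band_windows"] = [tuple(w) for w in payload["band_windows"]]
        return cls(**payload).validate()

    def override(self, **updates) -> "RunConfig":
        updates = {k: v for k, v in updates.items() if v is not None}
        return dataclasses.replace(self, **updates).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
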