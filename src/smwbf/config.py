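"""Pipeline configuration loaded from a JSON file.

Schema (all keys optional, defaults shown):

    {
      "clustering": {"eps": 0.1, "min_samples": 1},
      "outlier":    {"threshold": 0.5},
      "padding":    {"p": 5, "image_w": 512, "image_h": 512},
      "iou_threshold": 0.9,
      "profiles": "profiles.csv",
      "seed": 0
    }

``profiles`` may instead be an inline list of
``{"detector_id": ..., "map50": ...}`` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .clustering import ClusterParams
from .fusion import OutlierParams, PaddingParams
from .weighting import DetectorProfile, read_profiles_csv

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    clustering: ClusterParams = field(default_factory=ClusterParams)
    outlier: OutlierParams = field(default_factory=OutlierParams)
    padding: PaddingParams = field(default_factory=PaddingParams)
    iou_threshold: float = 0.9
    profiles_path: str | None = None
    inline_profiles: tuple[DetectorProfile, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")

    @classmethod
    def from_dict(cls, d: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        profiles = d.get("profiles")
        profiles_path = None
        inline = None
        if isinstance(profiles, str):
            profiles_path = str(Path(base_dir) / profiles)
        elif isinstance(profiles, list):
            inline = tuple(
                DetectorProfile(str(p["detector_id"]), float(p["map50"]))
                for p in profiles
            )
        return cls(
            clustering=ClusterParams(**d.get("clustering", {})),
            outlier=OutlierParams(**d.get("outlier", {})),
            padding=PaddingParams(**d.get("padding", {})),
            iou_threshold=float(d.get("iou_threshold", 0.9)),
            profiles_path=profiles_path,
            inline_profiles=inline,
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        return cls.from_dict(json.loads(path.read_text()), base_dir=path.parent)

    def load_profiles(self) -> list[DetectorProfile] | None:
        if self.inline_profiles is not None:
            return list(self.inline_profiles)
        if self.profiles_path is not None:
            return read_profiles_csv(self.profiles_path)
        return None
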