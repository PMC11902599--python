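"""Pipeline configuration: dataclass, YAML round-trip, key=value overrides.

Defaults are the reference rig's calibrated values: Lowe ratio 0.6 with a
single kd-tree index of 5 trees, disease threshold 110 counts,
reprojection scale s = 0.02, upsampling factor 5, and ExG as the matching
channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import CameraIntrinsics
from .spectral import CHANNEL_KINDS

__all__ = ["PipelineConfig", "load_config", "save_config", "apply_overrides"]


@dataclass
class PipelineConfig:
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    upsample_factor: int = 5
    match_ratio: float = 0.6
    ann_kdtree_indexes: int = 1      # backend provenance; see features.match_keypoints
    ann_trees: int = 5
    max_vertical_drift: float = 20.0  # px at native resolution
    disease_threshold: float = 110.0
    channel_for_matching: str = "exg"
    world_scale: float = 1.0
    densify_method: str = "linear"
    use_ransac: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_for_matching not in CHANNEL_KINDS:
            raise ValueError(f"channel_for_matching must be one of {CHANNEL_KINDS}")
        if not (0.0 < self.match_ratio <= 1.0):
            raise ValueError("match_ratio must lie in (0, 1]")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.disease_threshold < 0 or self.max_vertical_drift < 0:
            raise ValueError("thresholds must be non-negative")
        if self.densify_method not in ("linear", "nearest"):
            raise ValueError("densify_method must be 'linear' or 'nearest'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intrinsics"] = dataclasses.asdict(self.intrinsics)
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing keys take their defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    intr = data.pop("intrinsics", {})
    return PipelineConfig(intrinsics=CameraIntrinsics(**intr), **data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved config next to outputs for provenance."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes", "on")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def apply_overrides(cfg: PipelineConfig, overrides: list[str]) -> PipelineConfig:
    """Apply ``key=value`` overrides; dotted keys reach into intrinsics."""
    updates: dict = {}
    intr_updates: dict = {}
    for item in overrides:
        key, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key = key.strip()
        if key.startswith("intrinsics."):
            sub = key.split(".", 1)[1]
            intr_updates[sub] = _coerce(getattr(cfg.intrinsics, sub), raw)
        else:
            updates[key] = _coerce(getattr(cfg, key), raw)
    intr = (dataclasses.replace(cfg.intrinsics, **intr_updates)
            if intr_updates else cfg.intrinsics)
    return dataclasses.replace(cfg, intrinsics=intr, **updates)
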