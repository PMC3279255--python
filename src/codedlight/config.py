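"""Pipeline configuration: one flat set of thresholds with YAML loading.

Defaults mirror the physical system: the 48-frame pattern spec, the
10-neighbor / 2.5 mm-radius isolation filter ("less than 10 other points
in a sphere of 5 mm diameter"), the 5 mm mesh edge limit, and the
vertical-axis leaf-angle reference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # pattern spec
    pattern_width: int = 1024
    pattern_height: int = 768
    gray_levels: int = 8
    shift_period: int = 16
    line_width: int = 1
    # segmentation / binarization
    green_threshold: float = 20.0  # excess-green units, 8-bit scale
    contrast_floor: float = 0.05  # fraction of dynamic range
    # triangulation and cleanup
    max_gap_mm: float = 3.0
    filter_radius_mm: float = 2.5
    min_neighbors: int = 10
    smooth_radius_mm: float = 1.5  # 0 disables MLS denoising
    max_edge_mm: float = 5.0
    # traits
    leaf_angle_reference: str = "vertical_axis"  # or "camera_axis"
    pot_height_mm: float = 40.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pattern_width",
            "pattern_height",
            "gray_levels",
            "shift_period",
            "line_width",
            "contrast_floor",
            "max_gap_mm",
            "filter_radius_mm",
            "max_edge_mm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.pot_height_mm < 0 or self.min_neighbors < 0 or self.smooth_radius_mm < 0:
            raise ValueError(
                "pot_height_mm, min_neighbors and smooth_radius_mm must be >= 0"
            )
        if self.leaf_angle_reference not in ("vertical_axis", "camera_axis"):
            raise ValueError(
                f"unknown leaf_angle_reference {self.leaf_angle_reference!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def pattern_spec(self):
        from .patterns import PatternSpec

        return PatternSpec(
            width=self.pattern_width,
            height=self.pattern_height,
            gray_levels=self.gray_levels,
            shift_period=self.shift_period,
            line_width=self.line_width,
        )
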