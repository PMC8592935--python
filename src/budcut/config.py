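"""Run configuration: one flat YAML-backed record for every tunable.

Unknown keys are rejected so typos never silently fall back to defaults, and
the effective configuration is echoed into every machine-readable output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .geometry import GeometryConfig
from .segmentation import SegmentationConfig
from .yolo import LossWeights

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # segmentation
    open_radius: int = 2
    close_radius: int = 3
    area_threshold: int = 50
    hue_rotation: int = 0
    channel_scale: int = 255
    min_mean_redness: int = 160
    # geometry
    hough_threshold: int = 10
    hough_line_gap: int = 10
    hough_seed: int = 0
    min_length_frac: float = 0.3
    merge_angle_tol: float = 5.0
    merge_dist_tol: float = 5.0
    pair_max_separation: float = 18.0
    # evaluation
    success_threshold: float = 15.0
    iou_threshold: float = 0.5
    # anchors / loss
    anchor_k: int = 9
    lambda_cobox: float = 5.0
    lambda_obj: float = 1.0
    lambda_noobj: float = 0.5
    lambda_class: float = 1.0
    # run control
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            open_radius=self.open_radius,
            close_radius=self.close_radius,
            area_threshold=self.area_threshold,
            hue_rotation=self.hue_rotation,
            channel_scale=self.channel_scale,
            min_mean_redness=self.min_mean_redness,
        )

    def geometry(self) -> GeometryConfig:
        return GeometryConfig(
            hough_threshold=self.hough_threshold,
            hough_line_gap=self.hough_line_gap,
            hough_seed=self.hough_seed,
            min_length_frac=self.min_length_frac,
            merge_angle_tol=self.merge_angle_tol,
            merge_dist_tol=self.merge_dist_tol,
            pair_max_separation=self.pair_max_separation,
        )

    def loss_weights(self) -> LossWeights:
        return LossWeights(
            cobox=self.lambda_cobox,
            obj=self.lambda_obj,
            noobj=self.lambda_noobj,
            cls=self.lambda_class,
        )
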