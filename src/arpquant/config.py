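"""Run configuration: every tunable of every stage, with defaults.

Defaults mirror the standard acquisition and analysis settings for widefield
endocytic-patch movies (100x objective, two channels) and bead-motility
movies (20x objective, 70 s frame interval). The configuration round-trips
losslessly through YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class ImageConfig(BaseModel):
    # patch movies: 100x; bead movies: 20x (override pixel_size/frame_interval)
    pixel_size: float = Field(0.065, gt=0, description="um per pixel")
    frame_interval: float = Field(1.0, gt=0, description="s between frames")
    channel_names: list[str] = ["Las17", "Abp1"]


class DetectionConfig(BaseModel):
    diameter: float = Field(0.5, gt=0, description="blob estimated diameter, um")
    quality_threshold: float = Field(5.0, ge=0)
    median_filter_channels: list[str] = ["Las17"]


class LinkConfig(BaseModel):
    max_link_distance: float = Field(0.5, gt=0, description="um")
    gap_closing_distance: float = Field(0.5, gt=0, description="um")
    max_frame_gap: int = Field(2, ge=0)


class CurationConfig(BaseModel):
    separation_distance: float = Field(0.5, gt=0, description="um")
    min_track_length: int = Field(3, ge=1)


class PairingConfig(BaseModel):
    max_distance: float = Field(0.5, gt=0, description="um")
    max_time_gap: float = Field(10.0, ge=0, description="s")


class CalibrationConfig(BaseModel):
    # literature reference maximum molecule counts per channel; no defaults
    # are asserted as truth -- they must be supplied for real data.
    reference_counts: dict[str, float] = {}


class PatchMetricsConfig(BaseModel):
    internalization_threshold: float = Field(0.25, gt=0, description="um, strict >")


class PreprocessConfig(BaseModel):
    illumination_sigma: float = Field(2.0, gt=0, description="um, smoothing scale")
    background_radius: float = Field(2.5, gt=0, description="um, median radius")
    min_bleach_frames: int = Field(5, ge=2)


class BeadConfig(BaseModel):
    annulus_r_in: float = Field(4.0, gt=0, description="pixels")
    annulus_r_out: float = Field(15.0, gt=0, description="pixels")
    angular_bin_deg: float = Field(30.0, gt=0)
    velocity_window: int = Field(3, ge=1, description="frames, boxcar")
    max_diameter: float = Field(3.8, gt=0, description="um, exclusion rule")
    min_speed: float = Field(0.05, ge=0, description="um/min, direction fallback")
    peak_min_distance: float = Field(1.0, gt=0, description="um, bundle peaks")
    peak_width: float = Field(2.0, ge=0, description="pixels, bundle peaks")
    peak_prominence_mads: float = Field(3.0, gt=0)


class BiochemConfig(BaseModel):
    receptor_total: float = Field(0.05, gt=0, description="uM Arp2/3 complex")
    kd_bounds: tuple[float, float] = (1e-6, 1e3)
    kd_starts: list[float] = [0.01, 0.1, 1.0]
    slope_window: int = Field(5, ge=2, description="points, MPR sliding window")
    plateau_fraction: float = Field(0.05, gt=0, le=1.0)

    @field_validator("kd_bounds")
    @classmethod
    def _ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not 0 < v[0] < v[1]:
            raise ValueError("kd_bounds must satisfy 0 < lo < hi")
        return v


class RunConfig(BaseModel):
    """All tunables of every analysis stage, with serialisable defaults."""

    images: ImageConfig = ImageConfig()
    detection: DetectionConfig = DetectionConfig()
    linking: LinkConfig = LinkConfig()
    curation: CurationConfig = CurationConfig()
    pairing: PairingConfig = PairingConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    metrics: PatchMetricsConfig = PatchMetricsConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    beads: BeadConfig = BeadConfig()
    biochem: BiochemConfig = BiochemConfig()
    seed: int = 0

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = json.loads(self.model_dump_json())
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.model_validate(data)
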