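"""Pipeline configuration: one human-editable YAML file.

Every numeric decision of the pipeline appears here with its default —
acquisition geometry, growth-model parameters, segmentation thresholds,
kinetics and peak-detection tunables, and the random seed. Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Strict):
    pixel_size: float = 0.5  # um/px
    frame_interval: float = 3.0  # min
    n_slices: int = 11
    z_spacing: float = 0.8  # um
    gaussian_sd: float = 8.0  # counts
    poisson_scale: float = 1.0
    frame_shape: tuple[int, int] = (128, 288)  # (Y, X)
    origin: tuple[float, float] = (0.0, 0.0)
    z_blur_px_per_um: float = 0.6


class ModelConfig(_Strict):
    tube_width: float = 5.5  # um
    area_15min: float = 16.7  # um^2, slow-phase area at 15 min
    calibration_mode: str = "rate_at_60"  # rate_at_60 | late_window | rate
    calibration_target: float = 400.2  # um^2 (at 60 min) for rate_at_60
    jitter: float = 0.15
    n_post_frames: int = 22


class SegmentationConfig(_Strict):
    shape_fraction: float = 0.70
    peak_fraction: float = 0.005
    min_area_px: int = 10  # emergence threshold, sustained 2 frames


class KineticsConfig(_Strict):
    friedman_frames: int = 10
    min_observed_minutes: float = 60.0
    conversion_min_area: float = 100.0  # um^2
    deceleration_window: int = 3


class PeakConfig(_Strict):
    prominence: float = 0.2
    concordance_deg: float = 30.0
    arrest_decay_fraction: float = 0.10
    arrest_growth_fraction: float = 0.10
    second_tube_deg: float = 45.0
    branch_deg: float = 30.0


class SimulateConfig(_Strict):
    n_tubes: int = 12
    model: str = "bulging"  # bulging | protrusion
    scenario: str = "normal"  # normal | arrest | second_tube | branching
    channels: list[str] = Field(default_factory=lambda: ["cytoplasm", "vesicle"])
    event: str | None = None  # None | actin | mgu
    event_area_um2: float = 300.0


class PipelineConfig(_Strict):
    """Root configuration object; serializable to/from YAML."""

    seed: int = 0
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    peaks: PeakConfig = Field(default_factory=PeakConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )

    def acquisition_spec(self):
        from .synthetic_microscopy import AcquisitionSpec

        a = self.acquisition
        return AcquisitionSpec(
            pixel_size=a.pixel_size,
            frame_interval=a.frame_interval,
            n_slices=a.n_slices,
            z_spacing=a.z_spacing,
            gaussian_sd=a.gaussian_sd,
            poisson_scale=a.poisson_scale,
            frame_shape=tuple(a.frame_shape),
            origin=tuple(a.origin),
            z_blur_px_per_um=a.z_blur_px_per_um,
        )
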