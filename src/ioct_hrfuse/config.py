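"""Pipeline configuration: one namespaced document covering every stage.

Unknown keys are rejected (typos fail loudly), and every pipeline run
writes its fully resolved configuration beside the outputs so results are
reproducible from the artefacts alone.
"""
from __future__ import annotations

import os
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    n_frames: int = 60
    stationary_segments: list[tuple[int, int]] = [(10, 21), (35, 46)]
    jitter: float = 0.0
    speckle_looks: float = 4.0
    n_layers: int = 5
    scene_shape: tuple[int, int] = (360, 480)
    rect_size: tuple[int, int] = (140, 90)
    drift_step: float = 3.0


class TrackingConfig(_Section):
    min_len: int = 8
    tol_step: float = 1.5
    tol_total: float = 3.0
    seed_point: tuple[float, float] | None = None  # None: first manifest point
    lk_levels: int = 3
    lk_window: int = 21
    lk_max_iter: int = 30
    lk_eps: float = 0.01
    lk_max_residual: float = 12.0


class FusionConfig(_Section):
    theta_range: float = 5.0
    theta_step: float = 0.5
    t_range: float = 30.0
    ncc_floor: float | None = None  # e.g. 0.5 to drop badly registered frames


class QualityConfig(_Section):
    t_snr: float = 70.0
    t_cnr: float = 3.0
    t_enl: float = 10.0
    n_layers: int = 5
    background_roi: tuple[int, int] = (32, 32)
    homogeneous_roi: tuple[int, int] = (16, 8)
    contrast_roi: tuple[int, int] = (96, 12)
    inverse_log: bool = False

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (self.t_snr, self.t_cnr, self.t_enl)


class MetricsConfig(_Section):
    niqe_patch_size: int = 96


class ExportConfig(_Section):
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    per_subject: bool = False


class PipelineConfig(_Section):
    """All stage defaults plus the master seed for every random choice."""

    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    tracking: TrackingConfig = TrackingConfig()
    fusion: FusionConfig = FusionConfig()
    quality: QualityConfig = QualityConfig()
    metrics: MetricsConfig = MetricsConfig()
    export: ExportConfig = ExportConfig()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )
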