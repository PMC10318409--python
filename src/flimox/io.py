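"""File formats and configuration for the pipeline.

Image stacks travel as multi-page TIFF (one page per time point, or per
phase step for modulated FLIM stacks) with a JSON sidecar carrying the
acquisition metadata; tables are CSV (full precision, '.' decimal, UTF-8,
header row — pinned so re-runs are byte-identical); per-step summaries and
run reports are JSON.  Times are seconds since experiment start in files,
hours in rendered reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "default_schedule_path",
    "read_stack",
    "write_stack",
    "StackMetadata",
    "PipelineConfig",
    "CalibrationConfig",
    "ScheduleConfig",
    "AnalysisConfig",
    "SimulateConfig",
    "RunReport",
]


def default_schedule_path() -> Path:
    """Path to the packaged default step-test schedule YAML."""
    from importlib.resources import files

    return Path(str(files("flimox").joinpath("data/default_schedule.yaml")))


@dataclass
class StackMetadata:
    """Sidecar metadata for a TIFF stack."""

    pixel_size_um: float = 0.065
    frame_interval_s: float = 300.0
    modulation_frequency_hz: float | None = None
    start_time_s: float = 0.0
    axis: str = "time"  # or "phase"

    def timestamps(self, n: int) -> np.ndarray:
        return self.start_time_s + np.arange(n) * self.frame_interval_s


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(
    frames: np.ndarray, path: str | Path, metadata: StackMetadata | None = None
) -> None:
    """Write a (T, H, W) array as a multi-page TIFF plus JSON sidecar.

    Integer input is stored as 16-bit unsigned, float input as 32-bit float
    (lifetime images keep their NaNs).
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if np.issubdtype(frames.dtype, np.integer):
        data = frames.astype(np.uint16)
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = metadata or StackMetadata()
    _sidecar_path(path).write_text(json.dumps(meta.__dict__, indent=2))


def read_stack(path: str | Path) -> tuple[np.ndarray, StackMetadata]:
    """Read a multi-page TIFF and its sidecar; defaults with a warning if
    the sidecar is missing."""
    import warnings

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = StackMetadata(**json.loads(sidecar.read_text()))
    else:
        warnings.warn(f"no sidecar for {path.name}; assuming defaults")
        meta = StackMetadata()
    return frames, meta


# --------------------------------------------------------------------------
# pipeline configuration (strict schema: unknown keys rejected)
# --------------------------------------------------------------------------

class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tau0_ns: float = 526.0
    tau_ox_ns: float = 144.0
    o2_ox_fraction: float = 1.0
    temperature_c: float = 30.0
    modulation_frequency_hz: float = 550e3
    reference_lifetime_ns: float = 3.75


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    levels_percent: list[float] = Field(
        default=[0, 2, 4, 6, 8, 10, 15, 21, 100]
    )
    initial_hold_h: float = 4.0
    step_duration_h: float = 3.0
    sample_interval_min: float = 5.0


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    border_margin_um: float = 0.5
    min_iou: float = 0.2
    growth_window_h: list[float] | None = None
    pre_switch_window_h: list[float] = Field(default=[0.0, 8.0 + 5.0 / 60.0])
    post_switch_window_h: list[float] = Field(default=[8.0 + 10.0 / 60.0, 9.0])
    lifetime_method: str = "phase"


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str = "aerobic"
    n_chambers: int = 5
    duration_h: float = 9.0
    n_seed_cells: int = 2
    division_cv: float = 0.2
    response_time_constant_min: float = 37.0
    expression_rate: float = 850.0
    maturation_rate_per_h: float = 0.5
    o2_min: float = 1e-4
    bleaching_rate_per_h: float = 0.0
    induction_ramp_h: float = 9.0
    flim_image_shape: list[int] = Field(default=[16, 16])
    flim_noise_sd: float = 0.0
    flim_phase_steps: int = 8
    render: bool = False
    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.0
    background: float = 0.0
    render_noise_sd: float = 0.0


class PipelineConfig(BaseModel):
    """Validated end-to-end run configuration; every tunable of the
    pipeline is reachable from here.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "flimox_out"
    seed: int = 0
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True)
        )


@dataclass
class RunReport:
    """Headline numbers and provenance of one pipeline run."""

    preset: str
    parameters: dict
    headline: dict
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "preset": self.preset,
            "parameters": self.parameters,
            "headline": self.headline,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def render_text(self) -> str:
        lines = [f"flimox run report — preset: {self.preset}", ""]
        for key, value in sorted(self.headline.items()):
            lines.append(f"  {key}: {value}")
        if self.warnings:
            lines.append("")
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines)
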