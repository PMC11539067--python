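"""Configuration schema and loading.

All numeric defaults used by the pipeline live here, grouped by stage;
computational modules take their parameters as arguments, so a single
validated config object drives reproducible runs. Configs are YAML
files; an empty file yields all defaults and any out-of-range value is
reported by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .propulsion import PropulsionConfig
from .tracking import TrackConfig
from .wave_model import WaveParams

__all__ = ["PipelineConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration failed schema validation; message lists every
    offending key."""


class WaveSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    body_length_mm: float = Field(30.0, gt=0)
    n_segments: int = Field(50, ge=10)
    freq_hz: float = Field(2.5, gt=0)
    wavelength_bl: float = Field(1.0, gt=0)
    standing_amp_rad: float = Field(0.03, ge=0)
    standing_peak_pos: float = Field(0.25, ge=0, le=1)
    standing_width: float = Field(0.10, gt=0)
    travelling_amp_rad: float = Field(0.08, ge=0)
    caudal_growth_exp: float = Field(2.0, ge=0)
    stiffness_gamma: float = Field(1.0, ge=0, le=1)
    stiffness_onset: float = Field(0.5, ge=0, le=1)

    def to_params(self) -> WaveParams:
        return WaveParams(**self.model_dump())


class PropulsionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    water_density: float = Field(1000.0, gt=0)
    tail_span_mm: float = Field(4.0, gt=0)
    drag_coeff: float = Field(0.1, gt=0)
    wetted_area_mm2: float = Field(150.0, gt=0)
    speed_bracket_upper_bl_s: float = Field(20.0, gt=0)
    n_noise_reps: int = Field(20, ge=1)
    jitter_cv: float = Field(0.05, ge=0)

    def to_config(self) -> PropulsionConfig:
        return PropulsionConfig(
            water_density=self.water_density,
            tail_span_mm=self.tail_span_mm,
            drag_coeff=self.drag_coeff,
            wetted_area_mm2=self.wetted_area_mm2,
            speed_bracket_bl_s=(0.0, self.speed_bracket_upper_bl_s),
        )


class TrackingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_method: str = "automatic"
    fixed_threshold: float = 128.0
    polarity: str = "dark-fish"
    min_blob_px: int = Field(50, ge=1)
    n_midline_points: int = Field(51, ge=11)
    smoothing_window: int = Field(7, ge=1)

    def to_config(self) -> TrackConfig:
        return TrackConfig(**self.model_dump())


class ArenaSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_mm: float = Field(172.0, gt=0)
    height_mm: float = Field(44.0, gt=0)
    stream_speed_label: str = "medium"
    centre_band_frac: float = Field(1.0 / 3.0, gt=0, le=1)


class EphysSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fs_hz: float = Field(25_000.0, gt=1000)
    bandpass_low_hz: float = Field(300.0, gt=0)
    bandpass_high_hz: float = Field(500.0, gt=0)
    notch_q: float = Field(30.0, gt=0)
    k_mad: float = Field(5.0, gt=0)
    refractory_ms: float = Field(2.0, gt=0)


class StatsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_resamples: int = Field(200_000, ge=1)
    statistic: str = "median_diff"
    bootstrap_n: int = Field(1000, ge=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wave: WaveSection = WaveSection()
    propulsion: PropulsionSection = PropulsionSection()
    tracking: TrackingSection = TrackingSection()
    arena: ArenaSection = ArenaSection()
    ephys: EphysSection = EphysSection()
    stats: StatsSection = StatsSection()
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; missing keys take defaults.

    Raises :class:`ConfigError` listing every offending key on schema
    violation; an empty or absent file yields all defaults.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {problems}") from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
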