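"""Pipeline configuration: defaults, JSON loading, strict validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


class ConfigError(ValueError):
    """Configuration file or values are invalid."""


@dataclass
class PipelineConfig:
    """All tunables of the extraction pipeline.

    Notable defaults: dispersion_threshold 0.001 (the reference
    interference threshold on the ratio-sample dispersion);
    transition_threshold_rad 2*pi/3 (turning angle marking a breath
    transition); basis_p/basis_s None means auto (about four Gaussian
    bumps per expected breath, neighbour-overlapping widths).
    """

    grid_rate: float = 20.0  # samples/s of the uniform grid
    subcarrier: int | None = None  # None = middle available subcarrier
    static_mode: str = "prefix"  # "prefix" | "moving"
    static_window_s: float = 10.0
    ratio_on_dynamic: bool = False  # ratio the static-removed series instead
    amp_floor_factor: float = 1e-3
    dispersion_window_s: float = 0.15
    dispersion_stride_s: float = 0.05
    dispersion_threshold: float = 0.001
    mask_close_gap_s: float = 1.0
    basis_p: int | None = None
    basis_s: float | None = None
    expected_breath_period_s: float = 4.0
    ridge: float = 1e-8
    transition_threshold_rad: float = 2.0943951023931953  # 2*pi/3
    min_separation_s: float = 0.8
    angle_lag_s: float = 0.8
    refine_transitions: bool = True
    gp_length_scale_min: float = 0.05
    gp_length_scale_max: float = 0.4
    gp_max_fit_samples: int = 192
    acc_gate_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rate <= 0:
            raise ConfigError("grid_rate must be positive")
        if self.static_mode not in ("prefix", "moving"):
            raise ConfigError("static_mode must be 'prefix' or 'moving'")
        if self.dispersion_threshold <= 0:
            raise ConfigError("dispersion_threshold must be positive")
        if self.angle_lag_s <= 0:
            raise ConfigError("angle_lag_s must be positive")
        if not 0 < self.transition_threshold_rad <= np.pi:
            raise ConfigError("transition_threshold_rad must lie in (0, pi]")
        if self.dispersion_window_s <= 0 or self.dispersion_stride_s <= 0:
            raise ConfigError("dispersion window and stride must be positive")
        if not 0 < self.gp_length_scale_min < self.gp_length_scale_max:
            raise ConfigError("GP length-scale bounds must be ordered and positive")
        if self.basis_p is not None and self.basis_p < 1:
            raise ConfigError("basis_p must be >= 1")
        if self.basis_s is not None and self.basis_s <= 0:
            raise ConfigError("basis_s must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config root must be a JSON object")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
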