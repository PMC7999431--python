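"""Run configuration: thresholds, windowing, simulator and hardware blocks.

Loaded from a nested key-value YAML file; every block is optional and falls
back to the calibrated package defaults.
"""

from __future__ import annotations

import os

import yaml
from pydantic import BaseModel, Field, model_validator

from .classify import Criteria
from .hardware import BatterySpec, DividerConfig, PowerBudget
from .synthetic import (
    DEFAULT_SAMPLE_INTERVAL_S,
    DEFAULT_SUPPLY_V,
    BehaviorParams,
    default_params,
)


class CriteriaConfig(BaseModel):
    stop_amp_v: float = 0.1
    amp_split_v: float = 0.5
    freq_split_hz: float = 1.0
    dvdt_split: float = 3.0

    def build(self) -> Criteria:
        return Criteria(**self.model_dump())


class WindowConfig(BaseModel):
    window_s: float = 5.0
    hop_s: float = 1.0
    smooth_len: int = 1

    @model_validator(mode="after")
    def _check(self) -> "WindowConfig":
        if self.window_s < 2.0:
            raise ValueError("window_s must be >= 2 s")
        if not (0 < self.hop_s <= self.window_s):
            raise ValueError("need 0 < hop_s <= window_s")
        if self.smooth_len < 1:
            raise ValueError("smooth_len must be >= 1")
        return self


class BehaviorParamsConfig(BaseModel):
    carrier_freq_hz: float | None = None
    amplitude_v: float | None = None
    baseline_v: float | None = None
    noise_sd_v: float | None = None
    dvdt_shape: str | None = None

    def build(self, label: str) -> BehaviorParams:
        base = default_params(label)
        patch = {k: v for k, v in self.model_dump().items() if v is not None}
        return BehaviorParams(
            label=label,
            carrier_freq_hz=patch.get("carrier_freq_hz", base.carrier_freq_hz),
            amplitude_v=patch.get("amplitude_v", base.amplitude_v),
            baseline_v=patch.get("baseline_v", base.baseline_v),
            noise_sd_v=patch.get("noise_sd_v", base.noise_sd_v),
            dvdt_shape=patch.get("dvdt_shape", base.dvdt_shape),
        )


class BatteryConfig(BaseModel):
    capacity_mah: float = 350.0
    current_ma: float = 25.0
    k_min: float = 1.1
    k_max: float = 1.3

    def build(self) -> BatterySpec:
        return BatterySpec(**self.model_dump())


class PowerConfig(BaseModel):
    components: dict[str, float] = Field(
        default_factory=lambda: {
            "mcu": 7.0,
            "bluetooth": 18.0,
            "temp_sensor": 0.0,
            "pressure_sensor": 0.0,
        }
    )
    v_dd: float = 3.3

    def build(self) -> PowerBudget:
        return PowerBudget(tuple(self.components.items()), self.v_dd)


class DividerSettings(BaseModel):
    v_in: float = 3.3
    r_load: float = 10_000.0

    def build(self) -> DividerConfig:
        return DividerConfig(**self.model_dump())


class HardwareConfig(BaseModel):
    battery: BatteryConfig = Field(default_factory=BatteryConfig)
    power: PowerConfig = Field(default_factory=PowerConfig)
    divider: DividerSettings = Field(default_factory=DividerSettings)
    v_ref: float = DEFAULT_SUPPLY_V


class RunConfig(BaseModel):
    """Top-level configuration for the CLI and pipeline helpers."""

    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    windowing: WindowConfig = Field(default_factory=WindowConfig)
    simulator: dict[str, BehaviorParamsConfig] = Field(default_factory=dict)
    hardware: HardwareConfig = Field(default_factory=HardwareConfig)
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S
    seed: int = 0
    log_level: str = "INFO"

    def behavior_params(self, label: str) -> BehaviorParams:
        if label in self.simulator:
            return self.simulator[label].build(label)
        return default_params(label)


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML config; ``None`` or a missing block means defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
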