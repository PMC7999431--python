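"""Closed-form device models for the smart-patch electronics.

Covers the resistive-sensor voltage divider, the microcontroller's 8-bit ADC,
Peukert's battery-lifetime law, the component power budget at the regulated
3.3 V rail, and the exponential RSSI-versus-distance decay fit used to
characterize the Bluetooth link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import RssiSample


@dataclass(frozen=True)
class DividerConfig:
    """Voltage divider at the sensing node: supply ``v_in`` across the
    series pair (sensor, load), output tapped over the load resistor."""

    v_in: float
    r_load: float

    def __post_init__(self) -> None:
        if self.v_in <= 0:
            raise ValueError(f"v_in must be > 0 V, got {self.v_in}")
        if self.r_load <= 0:
            raise ValueError(f"r_load must be > 0 ohm, got {self.r_load}")


@dataclass(frozen=True)
class BatterySpec:
    """Battery capacity/current pair with a Peukert-coefficient range."""

    capacity_mah: float
    current_ma: float
    k_min: float = 1.1
    k_max: float = 1.3

    def __post_init__(self) -> None:
        if self.capacity_mah <= 0:
            raise ValueError("capacity_mah must be > 0")
        if self.current_ma <= 0:
            raise ValueError("current_ma must be > 0")
        if not (1.0 <= self.k_min <= self.k_max):
            raise ValueError(
                f"need 1 <= k_min <= k_max, got [{self.k_min}, {self.k_max}]"
            )


@dataclass(frozen=True)
class PowerBudget:
    """Per-component current draws (mA) and the supply they run from."""

    components: Sequence[tuple[str, float]] = field(
        default_factory=lambda: (
            ("mcu", 7.0),
            ("bluetooth", 18.0),
            ("temp_sensor", 0.0),
            ("pressure_sensor", 0.0),
        )
    )
    v_dd: float = 3.3

    def __post_init__(self) -> None:
        if self.v_dd <= 0:
            raise ValueError("v_dd must be > 0 V")
        for name, ma in self.components:
            if ma < 0:
                raise ValueError(f"negative current for {name!r}: {ma} mA")


@dataclass(frozen=True)
class RssiFit:
    """Fitted parameters of RSSI(d) = r0 * exp(d / lambda)."""

    r0_dbm: float
    lambda_m: float
    residual_rms_db: float

    def __post_init__(self) -> None:
        if self.lambda_m <= 0:
            raise ValueError("lambda_m must be > 0")

    def predict(self, distance_m):
        """Model RSSI (dBm) at the given distance(s)."""
        return self.r0_dbm * np.exp(np.asarray(distance_m, dtype=float) / self.lambda_m)


# --------------------------------------------------------------------------
# Voltage divider


def divider_vout(cfg: DividerConfig, r_sensor: float) -> float:
    """Sensing-node output voltage V_in * R_L / (R_L + R_S).

    Strictly decreasing in the sensor resistance: pressure lowers R_S and
    raises the output.
    """
    if r_sensor < 0:
        raise ValueError(f"sensor resistance must be >= 0 ohm, got {r_sensor}")
    return cfg.v_in * cfg.r_load / (cfg.r_load + r_sensor)


def divider_rsensor(cfg: DividerConfig, v_out: float) -> float:
    """Invert the divider: sensor resistance implied by an output voltage."""
    if v_out <= 0:
        raise ValueError("v_out must be > 0 V (zero output implies infinite R_S)")
    if v_out > cfg.v_in:
        raise ValueError(f"v_out {v_out} V exceeds the applied voltage {cfg.v_in} V")
    return cfg.r_load * (cfg.v_in - v_out) / v_out


# --------------------------------------------------------------------------
# 8-bit ADC


def adc_quantize(v, v_ref: float = 3.3, bits: int = 8):
    """Convert voltage(s) to integer ADC code(s), round-half-up.

    Input is clamped to [0, v_ref]; full scale maps to ``2**bits - 1``.
    """
    if v_ref <= 0:
        raise ValueError("v_ref must be > 0 V")
    if bits < 1:
        raise ValueError("bits must be >= 1")
    full = 2**bits - 1
    x = np.clip(np.asarray(v, dtype=float), 0.0, v_ref) / v_ref * full
    code = np.floor(x + 0.5).astype(int)  # round-half-up, MCU style
    return code if code.ndim else int(code)


def adc_dequantize(code, v_ref: float = 3.3, bits: int = 8):
    """Map ADC code(s) back to voltage(s): ``code / (2**bits - 1) * v_ref``."""
    if v_ref <= 0:
        raise ValueError("v_ref must be > 0 V")
    if bits < 1:
        raise ValueError("bits must be >= 1")
    v = np.asarray(code, dtype=float) / (2**bits - 1) * v_ref
    return v if v.ndim else float(v)


# --------------------------------------------------------------------------
# Battery lifetime (Peukert)


def peukert_lifetime(spec: BatterySpec, k: float) -> float:
    """Operating time in hours, t = C / I**k.

    Evaluated with C in mAh and I in mA as printed on the device datasheet;
    the mixed units are deliberate (see the methods note on the law's
    dimensional caveat).
    """
    if k < 1:
        raise ValueError(f"Peukert coefficient must be >= 1, got {k}")
    return spec.capacity_mah / spec.current_ma**k


def lifetime_range(spec: BatterySpec) -> tuple[float, float]:
    """(midpoint, half-range) of the lifetime over the coefficient range."""
    t_lo = peukert_lifetime(spec, spec.k_max)  # larger k, shorter life
    t_hi = peukert_lifetime(spec, spec.k_min)
    return (t_hi + t_lo) / 2.0, (t_hi - t_lo) / 2.0


# --------------------------------------------------------------------------
# Power budget


def power_budget(budget: PowerBudget) -> tuple[dict[str, float], float]:
    """Per-component power in mW (I * V_DD) and the total current in mA."""
    powers = {name: ma * budget.v_dd for name, ma in budget.components}
    total_ma = float(sum(ma for _, ma in budget.components))
    return powers, total_ma


# --------------------------------------------------------------------------
# RSSI-distance decay fit


def fit_rssi_decay(samples: Sequence[RssiSample]) -> RssiFit:
    """Least-squares fit of RSSI(d) = r0 * exp(d / lambda), r0 < 0.

    The fit is linear regression of ln|RSSI| on distance; the signal level is
    negative everywhere so the magnitude grows by a factor e every ``lambda``
    meters. Replicate distances are allowed and weighted naturally by the
    regression.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit the decay")
    d = np.array([s.distance_m for s in samples], dtype=float)
    r = np.array([s.rssi_dbm for s in samples], dtype=float)
    if np.any(r >= 0):
        raise ValueError("all RSSI values must be negative (dBm below 0)")
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct distances")
    result = stats.linregress(d, np.log(-r))
    if not math.isfinite(result.slope) or result.slope <= 1e-12:
        raise ValueError(
            "degenerate fit: RSSI magnitude does not grow with distance"
        )
    lam = 1.0 / result.slope
    r0 = -math.exp(result.intercept)
    resid = r - r0 * np.exp(d / lam)
    return RssiFit(r0_dbm=r0, lambda_m=lam, residual_rms_db=float(np.sqrt(np.mean(resid**2))))
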