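"""Labeled synthetic flipper-sensor traces for the four signature behaviors.

No recorded seal data are distributed with the device, so every downstream
stage is exercised on phenomenological waveforms whose sampled features are
calibrated to sit safely inside each behavior's threshold signature at the
device's 6.25 Hz stream rate (one sample per 160 ms transmission):

* ``stop`` — flat baseline plus small Gaussian noise.
* ``rolling`` — a two-harmonic 1.25 Hz oscillation (fundamental plus second
  harmonic). A pure sinusoid cannot represent rolling: any sinusoid with
  f > 1 Hz and amplitude > 0.5 V has a peak derivative 2*pi*f*A > 3 V/s,
  outside the rolling signature. The harmonic mix keeps the sampled
  central-difference derivative at 2.5 V/s while the dominant spectral line
  stays above 1 Hz.
* ``flapping`` — a slow 0.625 Hz carrier with one impulsive biphasic kick
  per cycle: the kick swings the signal across its full amplitude within two
  sample intervals, driving the sampled derivative to A/dt = 3.44 V/s > 3
  without raising the dominant frequency above 1 Hz.
* ``sliding`` — a random-phase multisine (four incommensurate tones between
  0.30 and 0.85 Hz) plus noise: band-limited, no single dominant
  periodicity, window amplitude well inside (0.1, 0.5) V.

Carrier periods are integer multiples of the 0.16 s sample interval
(rolling 0.8 s = 5 samples, flapping 1.6 s = 10 samples) so the sampled
waveform is phase-stable and its discrete derivative exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import BehaviorLabel, BehaviorSegment
from .io import RssiSample, SignalTrace

#: Device sampling period: one value per Bluetooth access, every 160 ms.
DEFAULT_SAMPLE_INTERVAL_S = 0.16

#: Regulated analog supply rail; generated voltages are clipped to [0, this].
DEFAULT_SUPPLY_V = 3.3

#: Resting sensor-node voltage. Not a measured value: the divider is most
#: sensitive when the load matches the sensor resistance, which places the
#: resting output near half the 3.3 V rail.
DEFAULT_BASELINE_V = 1.65

_VALID_LABELS = ("stop", "rolling", "flapping", "sliding")
_VALID_SHAPES = ("flat", "sine", "biharmonic", "impulsive", "band_noise")

# Rolling: normalized w(p) = C1*sin(2*pi*p) - C2*sin(4*pi*p); at 5 samples
# per period the sample pattern is [0, .538, 1, -1, -.538] with unit peak.
_ROLL_C1 = 0.8799177619105725
_ROLL_C2 = 0.5076443376180532

# Flapping: carrier fraction of the amplitude, and the kick height that
# brings the two samples flanking the upward zero crossing to exactly +/-A.
_FLAP_CARRIER = 0.45 / 0.55
_FLAP_KICK = 1.0 - _FLAP_CARRIER * math.sin(0.2 * math.pi)

# Sliding multisine: tone frequencies relative to carrier_freq_hz and their
# weights relative to amplitude_v.
_SLIDE_FREQ_RATIOS = np.array([0.30, 0.45, 0.62, 0.85]) / 0.55
_SLIDE_WEIGHTS = np.array([0.14, 0.12, 0.10, 0.08]) / 0.35


@dataclass(frozen=True)
class BehaviorParams:
    """Waveform parameters for one behavior's generator.

    ``dvdt_shape`` selects the waveform family and thereby the derivative
    magnitude achievable at fixed amplitude (see the module docstring).
    """

    label: str
    carrier_freq_hz: float
    amplitude_v: float
    baseline_v: float = DEFAULT_BASELINE_V
    noise_sd_v: float = 0.01
    dvdt_shape: str = "sine"

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValueError(
                f"unknown behavior {self.label!r}; expected one of {_VALID_LABELS}"
            )
        if self.dvdt_shape not in _VALID_SHAPES:
            raise ValueError(
                f"unknown dvdt_shape {self.dvdt_shape!r}; "
                f"expected one of {_VALID_SHAPES}"
            )
        if self.amplitude_v < 0 or self.noise_sd_v < 0 or self.carrier_freq_hz < 0:
            raise ValueError("amplitude, noise sd and carrier frequency must be >= 0")
        if not (
            0 <= self.baseline_v - self.amplitude_v
            and self.baseline_v + self.amplitude_v <= DEFAULT_SUPPLY_V
        ):
            raise ValueError(
                f"baseline {self.baseline_v} +/- amplitude {self.amplitude_v} "
                f"leaves the [0, {DEFAULT_SUPPLY_V}] V supply range"
            )

    @property
    def max_component_freq_hz(self) -> float:
        """Highest tone frequency the waveform contains (Nyquist check)."""
        if self.dvdt_shape == "band_noise":
            return self.carrier_freq_hz * float(_SLIDE_FREQ_RATIOS[-1])
        if self.dvdt_shape == "biharmonic":
            return 2.0 * self.carrier_freq_hz
        return self.carrier_freq_hz


def default_params(label: str) -> BehaviorParams:
    """Calibrated defaults whose sampled features satisfy the label's
    threshold signature exactly at zero noise."""
    try:
        return _DEFAULTS[label]
    except KeyError:
        raise ValueError(
            f"unknown behavior {label!r}; expected one of {_VALID_LABELS}"
        ) from None


_DEFAULTS = {
    "stop": BehaviorParams("stop", 0.0, 0.0, noise_sd_v=0.01, dvdt_shape="flat"),
    "rolling": BehaviorParams(
        "rolling", 1.25, 0.52, noise_sd_v=0.01, dvdt_shape="biharmonic"
    ),
    "flapping": BehaviorParams(
        "flapping", 0.625, 0.55, noise_sd_v=0.01, dvdt_shape="impulsive"
    ),
    "sliding": BehaviorParams(
        "sliding", 0.55, 0.28, noise_sd_v=0.015, dvdt_shape="band_noise"
    ),
}


@dataclass(frozen=True)
class SessionScript:
    """An ordered list of behavior bouts making up one recording session."""

    entries: Sequence[tuple[str, float]]
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # label -> BehaviorParams

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a session script needs at least one entry")
        for label, duration in self.entries:
            if label not in _VALID_LABELS:
                raise ValueError(
                    f"unknown behavior {label!r}; expected one of {_VALID_LABELS}"
                )
            if duration <= 0:
                raise ValueError(f"bout durations must be > 0 s, got {duration}")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.entries))


def _kick(p: np.ndarray) -> np.ndarray:
    """Biphasic unit kick around phase 0: -1 at p=-0.1, +1 at p=+0.1."""
    p = (p + 0.5) % 1.0 - 0.5  # wrap to [-0.5, 0.5)
    out = np.zeros_like(p)
    core = np.abs(p) <= 0.1
    out[core] = np.sin(5.0 * np.pi * p[core])
    taper = (np.abs(p) > 0.1) & (np.abs(p) <= 0.2)
    out[taper] = np.sign(p[taper]) * (2.0 - 10.0 * np.abs(p[taper]))
    return out


def _waveform(
    params: BehaviorParams, t_local: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Noiseless waveform (deviation from baseline, volts) at local times."""
    shape, A, f = params.dvdt_shape, params.amplitude_v, params.carrier_freq_hz
    if shape == "flat" or A == 0.0:
        return np.zeros_like(t_local)
    p = f * t_local
    if shape == "sine":
        return A * np.sin(2.0 * np.pi * p)
    if shape == "biharmonic":
        return A * (
            _ROLL_C1 * np.sin(2.0 * np.pi * p) - _ROLL_C2 * np.sin(4.0 * np.pi * p)
        )
    if shape == "impulsive":
        return A * (_FLAP_CARRIER * np.sin(2.0 * np.pi * p) + _FLAP_KICK * _kick(p))
    # band_noise: random-phase multisine; phases drawn once per bout.
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_SLIDE_FREQ_RATIOS))
    tones = np.sin(
        2.0 * np.pi * np.outer(_SLIDE_FREQ_RATIOS * f, t_local)
        + phases[:, None]
    )
    return A * (_SLIDE_WEIGHTS @ tones)


def _n_samples(duration_s: float, dt: float) -> int:
    # floor with a small guard so exact multiples are not lost to float error
    return int(math.floor(duration_s / dt + 1e-9))


def generate_behavior_trace(
    params: BehaviorParams,
    duration_s: float,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
    seed: int = 0,
    *,
    supply_v: float = DEFAULT_SUPPLY_V,
    quantize_bits: int | None = None,
) -> SignalTrace:
    """Generate one single-behavior trace of floor(duration/interval) samples.

    Deterministic: identical arguments and seed give bit-identical traces.
    Voltages are clipped to [0, supply]; ``quantize_bits`` optionally passes
    the signal through the ADC model (quantize + dequantize), emulating the
    8-bit stream the phone actually receives.
    """
    if duration_s < 2 * sample_interval_s:
        raise ValueError(
            f"duration {duration_s} s must be at least two sample intervals "
            f"({2 * sample_interval_s} s)"
        )
    nyquist = 0.5 / sample_interval_s
    if params.max_component_freq_hz >= nyquist:
        raise ValueError(
            f"waveform content at {params.max_component_freq_hz:g} Hz is at or "
            f"above the Nyquist frequency {nyquist:g} Hz for a "
            f"{sample_interval_s:g} s sampling interval"
        )
    n = _n_samples(duration_s, sample_interval_s)
    times = np.arange(n) * sample_interval_s
    rng = np.random.default_rng(seed)
    volts = params.baseline_v + _waveform(params, times, rng)
    if params.noise_sd_v > 0:
        volts = volts + rng.normal(0.0, params.noise_sd_v, size=n)
    volts = np.clip(volts, 0.0, supply_v)
    meta: dict[str, object] = {
        "label": params.label,
        "seed": seed,
        "supply_v": supply_v,
        "noise_sd_v": params.noise_sd_v,
    }
    if quantize_bits is not None:
        from .hardware import adc_dequantize, adc_quantize

        codes = adc_quantize(volts, supply_v, quantize_bits)
        volts = adc_dequantize(codes, supply_v, quantize_bits)
        meta["adc_bits"] = quantize_bits
        meta["v_ref"] = supply_v
        meta["adc_codes"] = codes
    return SignalTrace(times, volts, sample_interval_s, meta)


def generate_session(
    script: SessionScript,
    *,
    supply_v: float = DEFAULT_SUPPLY_V,
    quantize_bits: int | None = None,
) -> tuple[SignalTrace, list[BehaviorSegment]]:
    """Concatenate behavior bouts on one continuous time axis.

    Returns the trace and the exact ground-truth partition of the timeline.
    Each bout's waveform phase restarts at the bout's first sample; each bout
    draws from an independent child seed of ``script.seed`` so editing one
    bout never shifts another's noise.
    """
    dt = script.sample_interval_s
    n = _n_samples(script.total_duration_s, dt)
    if n < 2:
        raise ValueError("session too short: fewer than 2 samples")
    times = np.arange(n) * dt
    volts = np.zeros(n)
    truth: list[BehaviorSegment] = []
    t_start = 0.0
    for i, (label, duration) in enumerate(script.entries):
        t_end = t_start + duration
        params = script.overrides.get(label, default_params(label))
        mask = (times >= t_start - 1e-9) & (times < t_end - 1e-9)
        idx = np.nonzero(mask)[0]
        rng = np.random.default_rng([script.seed, i])
        if len(idx):
            local = times[idx] - times[idx[0]]
            bout = params.baseline_v + _waveform(params, local, rng)
            if params.noise_sd_v > 0:
                bout = bout + rng.normal(0.0, params.noise_sd_v, size=len(idx))
            volts[idx] = bout
        truth.append(BehaviorSegment(BehaviorLabel(label), t_start, t_end))
        t_start = t_end
    volts = np.clip(volts, 0.0, supply_v)
    meta: dict[str, object] = {
        "script": ";".join(f"{lab}:{dur:g}" for lab, dur in script.entries),
        "seed": script.seed,
        "supply_v": supply_v,
    }
    if quantize_bits is not None:
        from .hardware import adc_dequantize, adc_quantize

        codes = adc_quantize(volts, supply_v, quantize_bits)
        volts = adc_dequantize(codes, supply_v, quantize_bits)
        meta["adc_bits"] = quantize_bits
        meta["v_ref"] = supply_v
        meta["adc_codes"] = codes
    return SignalTrace(times, volts, dt, meta), truth


def generate_rssi_samples(
    r0_dbm: float,
    lambda_m: float,
    distances: Sequence[float],
    noise_sd_db: float = 0.0,
    seed: int = 0,
) -> list[RssiSample]:
    """Draw RSSI(d) = r0 * exp(d / lambda) + Gaussian noise at each distance.

    With negative ``r0_dbm`` the signal magnitude grows by a factor e every
    ``lambda_m`` meters. Repeated distances model replicate measurements.
    """
    if lambda_m <= 0:
        raise ValueError(f"lambda_m must be > 0 m, got {lambda_m}")
    if noise_sd_db < 0:
        raise ValueError("noise_sd_db must be >= 0")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0 m")
    rng = np.random.default_rng(seed)
    rssi = r0_dbm * np.exp(d / lambda_m)
    if noise_sd_db > 0:
        rssi = rssi + rng.normal(0.0, noise_sd_db, size=len(d))
    return [RssiSample(float(di), float(ri)) for di, ri in zip(d, rssi)]
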