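"""Window feature extraction: amplitude, dominant frequency, dV/dt.

These are the three analyzers feeding the threshold ethogram classifier,
plus a hysteresis sign-transition counter on the derivative used to count
rolling cycles. All features are computed on the device's sampled stream;
the decision thresholds therefore apply to discrete-time quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import SignalTrace

#: Default hysteresis for derivative sign-transition counting, V/s. One LSB
#: of the 8-bit stream per sample is 3.3/255/0.16 ~ 0.08 V/s; 0.1 suppresses
#: quantization chatter without masking real cycle endings (>1 V/s swings).
DEFAULT_HYSTERESIS = 0.1

#: A periodogram peak counts as a real spectral line when it exceeds this
#: multiple of the median non-DC spectral power; otherwise the estimator
#: falls back to the zero-crossing rate.
PEAK_PROMINENCE_FACTOR = 4.0


@dataclass(frozen=True)
class FeatureVector:
    """Per-window (frequency, amplitude, dV/dt amplitude) triple."""

    frequency_hz: float
    amplitude_v: float
    dvdt_amp: float

    def __post_init__(self) -> None:
        for name in ("frequency_hz", "amplitude_v", "dvdt_amp"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")


def amplitude_analyzer(window: SignalTrace) -> float:
    """Peak deviation from the window baseline, max |v - median(v)|.

    The median baseline is robust to impulsive waveforms whose mean is pulled
    toward the spikes; a constant window reports exactly 0. Invariant to
    baseline shifts and to sign flips about the baseline.
    """
    v = window.voltages
    if len(v) < 2:
        raise ValueError("amplitude analyzer needs at least 2 samples")
    return float(np.max(np.abs(v - np.median(v))))


def frequency_analyzer(window: SignalTrace) -> float:
    """Dominant oscillation frequency of the window, in Hz.

    Uses the non-DC periodogram argmax when a clear spectral line exists
    (peak power above ``PEAK_PROMINENCE_FACTOR`` times the median non-DC
    power); otherwise estimates frequency as zero crossings of the
    mean-removed signal divided by twice the window duration. Quasi-constant
    windows report 0.
    """
    v = window.voltages
    duration = window.duration_s
    if duration < 2.0 - 1e-9:
        raise ValueError(
            f"window spans {duration:.3f} s; need >= 2 s for 0.5 Hz resolution "
            "around the 1 Hz decision boundary"
        )
    fs = 1.0 / window.sample_interval_s
    freqs, power = sps.periodogram(v, fs=fs, detrend="constant")
    freqs, power = freqs[1:], power[1:]  # drop DC
    if len(power) and np.max(power) > PEAK_PROMINENCE_FACTOR * np.median(power):
        return float(freqs[int(np.argmax(power))])
    centered = v - np.mean(v)
    signs = np.sign(centered)
    signs = signs[signs != 0]  # exact-baseline samples carry no crossing info
    if len(signs) < 2:
        return 0.0
    crossings = int(np.count_nonzero(np.diff(signs)))
    return crossings / (2.0 * duration)


def differentiator(trace: SignalTrace, smooth_len: int = 1) -> SignalTrace:
    """dV/dt trace: central finite differences, one-sided at the ends.

    ``smooth_len`` applies a moving average (boxcar, nearest-edge padding)
    before differencing; 1 means no smoothing. The output trace shares the
    input time axis and flags its units as V/s in the metadata.
    """
    if len(trace) < 3:
        raise ValueError("differentiator needs at least 3 samples")
    if smooth_len < 1:
        raise ValueError("smooth_len must be >= 1")
    if smooth_len > len(trace):
        raise ValueError(
            f"smooth_len {smooth_len} exceeds trace length {len(trace)}"
        )
    v = trace.voltages
    if smooth_len > 1:
        v = uniform_filter1d(v, size=smooth_len, mode="nearest")
    deriv = np.gradient(v, trace.sample_interval_s)
    meta = dict(trace.meta)
    meta.pop("supply_v", None)  # derivative is not bounded by the supply
    meta["units"] = "V/s"
    meta["smooth_len"] = smooth_len
    return SignalTrace(trace.times, deriv, trace.sample_interval_s, meta)


def dvdt_amplitude(derivative: SignalTrace) -> float:
    """Max |dV/dt| over a derivative window; 0 for an all-zero window."""
    d = derivative.voltages
    if len(d) < 1:
        raise ValueError("empty derivative window")
    return float(np.max(np.abs(d)))


def count_cycle_endings(
    derivative: SignalTrace,
    direction: Literal["pos_to_neg", "neg_to_pos"] = "pos_to_neg",
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> tuple[int, list[float]]:
    """Count derivative sign transitions of one direction with hysteresis.

    A Schmitt-trigger walk over the samples: the state becomes positive when
    dV/dt > +hysteresis and negative when dV/dt < -hysteresis; transitions of
    the requested direction are counted at the sample where the new state is
    entered, and excursions smaller than the hysteresis band are ignored.
    Returns ``(count, event_times)``.
    """
    if direction not in ("pos_to_neg", "neg_to_pos"):
        raise ValueError(f"unknown direction {direction!r}")
    if hysteresis < 0:
        raise ValueError(f"hysteresis must be >= 0 V/s, got {hysteresis}")
    d = derivative.voltages
    if len(d) == 0:
        raise ValueError("empty derivative trace")
    want_from = 1 if direction == "pos_to_neg" else -1
    state = 0
    events: list[float] = []
    for i, value in enumerate(d):
        if value > hysteresis:
            new_state = 1
        elif value < -hysteresis:
            new_state = -1
        else:
            continue
        if state == want_from and new_state == -want_from:
            events.append(float(derivative.times[i]))
        state = new_state
    return len(events), events
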