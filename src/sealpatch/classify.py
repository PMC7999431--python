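"""Threshold decision algorithm over sliding windows.

The ethogram has four signature behaviors — stop, rolling, flapping,
sliding — each defined by which side of three fixed splits its window
features fall on (frequency vs 1 Hz, amplitude vs 0.5 V, dV/dt vs 3 V/s),
with a near-zero amplitude short-circuiting to STOP before any spectral
evaluation. Windows matching no signature are MOVING; a feature landing
exactly on a split is neither low nor high and yields ERROR, the cue to
re-tune the thresholds in the configuration rather than tie-break silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import features as feat
from .features import FeatureVector
from .io import SignalTrace


class BehaviorLabel(enum.Enum):
    STOP = "stop"
    ROLLING = "rolling"
    FLAPPING = "flapping"
    SLIDING = "sliding"
    MOVING = "moving"
    ERROR = "error"


#: The four generator-producible behaviors (excludes MOVING/ERROR outcomes).
SIGNATURE_LABELS = (
    BehaviorLabel.STOP,
    BehaviorLabel.ROLLING,
    BehaviorLabel.FLAPPING,
    BehaviorLabel.SLIDING,
)


@dataclass(frozen=True)
class Criteria:
    """Decision thresholds of the classification algorithm.

    stop_amp_v:
        Amplitudes below this are "low value (~0)" and classify as STOP.
    amp_split_v / freq_split_hz / dvdt_split:
        The high/low splits for the amplitude, frequency and derivative
        analyzers (0.5 V, 1 Hz, 3 V/s by default).
    """

    stop_amp_v: float = 0.1
    amp_split_v: float = 0.5
    freq_split_hz: float = 1.0
    dvdt_split: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.stop_amp_v < self.amp_split_v):
            raise ValueError(
                f"need 0 < stop_amp_v < amp_split_v, got "
                f"{self.stop_amp_v} vs {self.amp_split_v}"
            )
        if self.freq_split_hz <= 0 or self.dvdt_split <= 0:
            raise ValueError("freq_split_hz and dvdt_split must be > 0")


@dataclass(frozen=True)
class BehaviorSegment:
    """A labeled time interval with its aggregate window features."""

    label: BehaviorLabel
    t_start_s: float
    t_end_s: float
    features: FeatureVector | None = None

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError(
                f"segment must have t_end > t_start, got "
                f"[{self.t_start_s}, {self.t_end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


AnalyzerType = Literal["amplitude", "frequency", "dvdt"]

_SPLIT_ATTR = {
    "amplitude": "amp_split_v",
    "frequency": "freq_split_hz",
    "dvdt": "dvdt_split",
}


def is_low(value: float, analyzer_type: AnalyzerType, criteria: Criteria) -> bool:
    """Strictly-below test against the analyzer's split.

    Equality is neither low nor high; ``classify_window`` maps it to ERROR.
    """
    if analyzer_type not in _SPLIT_ATTR:
        raise ValueError(
            f"unknown analyzer type {analyzer_type!r}; "
            f"expected one of {sorted(_SPLIT_ATTR)}"
        )
    if value < 0:
        raise ValueError(f"analyzer outputs are non-negative, got {value}")
    return value < getattr(criteria, _SPLIT_ATTR[analyzer_type])


def classify_window(fv: FeatureVector, criteria: Criteria = Criteria()) -> BehaviorLabel:
    """Map one window's feature triple to a behavior label.

    STOP is decided first from the amplitude alone; then the three
    high/low tests select among the signature behaviors:

    ==========  =========  =========  ========
    label       frequency  amplitude  dV/dt
    ==========  =========  =========  ========
    ROLLING     > 1 Hz     > 0.5 V    < 3 V/s
    FLAPPING    < 1 Hz     > 0.5 V    > 3 V/s
    SLIDING     < 1 Hz     < 0.5 V    < 3 V/s
    ==========  =========  =========  ========

    Any other combination is MOVING; a feature exactly on a split is ERROR.
    """
    if fv.amplitude_v < criteria.stop_amp_v:
        return BehaviorLabel.STOP
    if (
        fv.amplitude_v == criteria.amp_split_v
        or fv.frequency_hz == criteria.freq_split_hz
        or fv.dvdt_amp == criteria.dvdt_split
    ):
        return BehaviorLabel.ERROR
    f_low = is_low(fv.frequency_hz, "frequency", criteria)
    a_low = is_low(fv.amplitude_v, "amplitude", criteria)
    d_low = is_low(fv.dvdt_amp, "dvdt", criteria)
    if not f_low and not a_low and d_low:
        return BehaviorLabel.ROLLING
    if f_low and not a_low and not d_low:
        return BehaviorLabel.FLAPPING
    if f_low and a_low and d_low:
        return BehaviorLabel.SLIDING
    return BehaviorLabel.MOVING


def window_features(window: SignalTrace, smooth_len: int = 1) -> FeatureVector:
    """Run the three analyzers on one standalone window.

    Note the derivative here is computed within the window, so its two edge
    samples use one-sided differences. The sliding-window pipeline instead
    differentiates the whole stream once and cuts windows from the
    derivative trace, avoiding edge artifacts (see ``classify_windows``).
    """
    deriv = feat.differentiator(window, smooth_len=smooth_len)
    return FeatureVector(
        frequency_hz=feat.frequency_analyzer(window),
        amplitude_v=feat.amplitude_analyzer(window),
        dvdt_amp=feat.dvdt_amplitude(deriv),
    )


def classify_windows(
    trace: SignalTrace,
    criteria: Criteria = Criteria(),
    window_s: float = 5.0,
    hop_s: float = 1.0,
    smooth_len: int = 1,
) -> list[tuple[float, BehaviorLabel, FeatureVector]]:
    """Per-window classification: (window center time, label, features).

    Windows are ``window_s`` long, advanced by ``hop_s``; both are snapped
    to whole samples. The label is assigned to the window center.
    """
    if window_s < 2.0:
        raise ValueError("window_s must be >= 2 s (frequency-analyzer resolution)")
    if hop_s > window_s:
        raise ValueError("hop_s must not exceed window_s")
    dt = trace.sample_interval_s
    n_win = int(round(window_s / dt))
    n_hop = max(1, int(round(hop_s / dt)))
    if n_win > len(trace):
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than one "
            f"{n_win}-sample window"
        )
    # Differentiate the whole stream once; windows then see only central
    # differences (the stream's own two endpoint samples are one-sided and
    # are excluded from the derivative maxima below).
    deriv = feat.differentiator(trace, smooth_len=smooth_len)
    out = []
    for start in range(0, len(trace) - n_win + 1, n_hop):
        stop = start + n_win
        window = trace.slice(start, stop)
        d_lo = max(start, 1)
        d_hi = min(stop, len(trace) - 1)
        fv = FeatureVector(
            frequency_hz=feat.frequency_analyzer(window),
            amplitude_v=feat.amplitude_analyzer(window),
            dvdt_amp=feat.dvdt_amplitude(deriv.slice(d_lo, d_hi)),
        )
        center = float(0.5 * (window.times[0] + window.times[-1]))
        out.append((center, classify_window(fv, criteria), fv))
    return out


def segment_session(
    trace: SignalTrace,
    criteria: Criteria = Criteria(),
    window_s: float = 5.0,
    hop_s: float = 1.0,
    smooth_len: int = 1,
) -> list[BehaviorSegment]:
    """Classify sliding windows and merge identical runs into segments.

    Each window's label covers [center - hop/2, center + hop/2); consecutive
    identical labels merge into maximal segments whose features are the mean
    of the member windows' features. Segment durations sum exactly to the
    covered timeline length.
    """
    labeled = classify_windows(trace, criteria, window_s, hop_s, smooth_len)
    dt = trace.sample_interval_s
    half_hop = max(1, int(round(hop_s / dt))) * dt / 2.0
    segments: list[BehaviorSegment] = []
    run_start = labeled[0][0] - half_hop
    run_label = labeled[0][1]
    run_feats: list[FeatureVector] = [labeled[0][2]]
    prev_center = labeled[0][0]
    for center, label, fv in labeled[1:]:
        if label is run_label:
            run_feats.append(fv)
            prev_center = center
            continue
        boundary = prev_center + half_hop
        segments.append(
            BehaviorSegment(run_label, run_start, boundary, _mean_features(run_feats))
        )
        run_start, run_label, run_feats = boundary, label, [fv]
        prev_center = center
    segments.append(
        BehaviorSegment(
            run_label, run_start, prev_center + half_hop, _mean_features(run_feats)
        )
    )
    return segments


def _mean_features(fvs: Sequence[FeatureVector]) -> FeatureVector:
    return FeatureVector(
        frequency_hz=float(np.mean([f.frequency_hz for f in fvs])),
        amplitude_v=float(np.mean([f.amplitude_v for f in fvs])),
        dvdt_amp=float(np.mean([f.dvdt_amp for f in fvs])),
    )


def summarize(
    segments: Sequence[BehaviorSegment],
    trace: SignalTrace | None = None,
    hysteresis: float = feat.DEFAULT_HYSTERESIS,
) -> dict[str, dict[str, float]]:
    """Per-label totals: segment count, total duration, roll-cycle count.

    Roll cycles are counted on each ROLLING segment's derivative as
    positive-to-negative dV/dt transitions (the ending point of each rolling
    cycle); this needs the source ``trace`` — without it roll counts are 0.
    """
    summary = {
        label.name: {"count": 0, "duration_s": 0.0, "rolls": 0}
        for label in BehaviorLabel
    }
    for seg in segments:
        entry = summary[seg.label.name]
        entry["count"] += 1
        entry["duration_s"] += seg.duration_s
        if seg.label is BehaviorLabel.ROLLING and trace is not None:
            mask = (trace.times >= seg.t_start_s - 1e-9) & (
                trace.times < seg.t_end_s - 1e-9
            )
            idx = np.nonzero(mask)[0]
            if len(idx) >= 3:
                sub = trace.slice(int(idx[0]), int(idx[-1]) + 1)
                deriv = feat.differentiator(sub)
                count, _ = feat.count_cycle_endings(
                    deriv, "pos_to_neg", hysteresis=hysteresis
                )
                entry["rolls"] += count
    return summary
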