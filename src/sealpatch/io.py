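"""Trace, segment and RSSI-table I/O with boundary validation.

All on-disk formats are plain CSV with a mandatory header row, ``.`` decimal
separator and optional ``#``-prefixed metadata comment lines (``# key=value``).
Times are always seconds, voltages always volts; there is no timestamp or
locale handling because the device emits a fixed-interval sample stream.
"""

from __future__ import annotations

import io as _stdio
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Tolerance on deviations of successive time differences from the nominal
#: sampling period (seconds).
UNIFORMITY_TOL_S = 1e-9

#: Decimal places used when formatting voltages (and derived quantities).
VOLTAGE_DECIMALS = 6

#: Decimal places used when formatting times; finer than UNIFORMITY_TOL_S so a
#: write/read round trip preserves the uniform-sampling invariant.
TIME_DECIMALS = 9


class TraceFormatError(ValueError):
    """Raised when an on-disk trace or table violates the format contract."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled sensor-node voltage time series.

    Parameters
    ----------
    times:
        Sample times in seconds, strictly increasing with uniform spacing.
    voltages:
        Sensor-node voltages in volts (or V/s for derivative traces, flagged
        via ``meta['units']``).
    sample_interval_s:
        Nominal sampling period in seconds. If omitted it is inferred from
        the median successive time difference.
    meta:
        Free-form provenance mapping (seed, generator parameters, source
        file). Serialized as ``# key=value`` comment lines.
    """

    times: np.ndarray
    voltages: np.ndarray
    sample_interval_s: float = 0.0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        voltages = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "voltages", voltages)
        if times.ndim != 1 or voltages.ndim != 1:
            raise TraceFormatError("times and voltages must be 1-D arrays")
        if len(times) != len(voltages):
            raise TraceFormatError(
                f"length mismatch: {len(times)} times vs {len(voltages)} voltages"
            )
        if len(times) < 2:
            raise TraceFormatError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(voltages)):
            raise TraceFormatError("times and voltages must be finite")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 2  # 1-based, second row of pair
            raise TraceFormatError(f"times must be strictly increasing (row {row})")
        if self.sample_interval_s:
            dt = float(self.sample_interval_s)
        else:
            # nominal period = most common interval (first seen wins ties),
            # so a single bad row is flagged rather than shifting the nominal
            counts: dict[float, int] = {}
            for d in np.round(diffs / UNIFORMITY_TOL_S) * UNIFORMITY_TOL_S:
                counts[float(d)] = counts.get(float(d), 0) + 1
            dt = max(counts, key=counts.get)
        dev = np.abs(diffs - dt)
        if np.any(dev > UNIFORMITY_TOL_S):
            row = int(np.argmax(dev > UNIFORMITY_TOL_S)) + 2
            raise TraceFormatError(
                f"non-uniform sampling at row {row}: interval "
                f"{diffs[row - 2]:.9f} s differs from {dt:.9f} s by more than "
                f"{UNIFORMITY_TOL_S:g} s"
            )
        object.__setattr__(self, "sample_interval_s", dt)
        supply = self.meta.get("supply_v") if self.meta else None
        if supply is not None:
            supply = float(supply)  # type: ignore[arg-type]
            if np.any(voltages < -1e-12) or np.any(voltages > supply + 1e-12):
                raise TraceFormatError(
                    f"voltages outside [0, {supply}] V declared supply range"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        """Time spanned by the samples, ``t[-1] - t[0]``."""
        return float(self.times[-1] - self.times[0])

    def slice(self, start: int, stop: int) -> "SignalTrace":
        """Return the sub-trace of samples ``start:stop`` (ndarray semantics)."""
        return SignalTrace(
            self.times[start:stop],
            self.voltages[start:stop],
            self.sample_interval_s,
            dict(self.meta),
        )


@dataclass(frozen=True)
class RssiSample:
    """One received-signal-strength measurement at a known distance."""

    distance_m: float
    rssi_dbm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.distance_m) or self.distance_m < 0:
            raise ValueError(f"distance must be finite and >= 0, got {self.distance_m}")
        if not math.isfinite(self.rssi_dbm):
            raise ValueError("rssi_dbm must be finite")


def _read_csv_with_meta(path: str | os.PathLike) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            lines.append(line)
    if not lines:
        raise TraceFormatError(f"{path}: no data rows")
    frame = pd.read_csv(_stdio.StringIO("".join(lines)))
    return frame, meta


def _write_meta(fh, meta: Mapping[str, object]) -> None:
    for key, value in meta.items():
        if key == "adc_codes":  # column data, not a scalar comment
            continue
        fh.write(f"# {key}={value}\n")


def read_trace(
    path: str | os.PathLike,
    *,
    time_column: str = "time_s",
    voltage_column: str = "voltage_v",
    adc_column: str = "adc_code",
    v_ref: float = 3.3,
) -> SignalTrace:
    """Read a trace CSV, validating uniform sampling at the boundary.

    If an ADC-code column is present, every code is checked against the
    voltage column through the 8-bit converter model: a stored voltage must
    lie within half an LSB of its dequantized code.
    """
    frame, meta = _read_csv_with_meta(path)
    for col in (time_column, voltage_column):
        if col not in frame.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r}; available: {list(frame.columns)}"
            )
    times = frame[time_column].to_numpy(dtype=float)
    volts = frame[voltage_column].to_numpy(dtype=float)
    trace = SignalTrace(times, volts, meta=meta)
    if adc_column in frame.columns:
        from .hardware import adc_dequantize

        codes = frame[adc_column].to_numpy(dtype=int)
        v_ref = float(meta.get("v_ref", v_ref))
        bits = int(meta.get("adc_bits", 8))
        lsb = v_ref / (2**bits - 1)
        err = np.abs(volts - adc_dequantize(codes, v_ref, bits))
        if np.any(err > 0.5 * lsb + 1e-12):
            row = int(np.argmax(err > 0.5 * lsb + 1e-12)) + 1
            raise TraceFormatError(
                f"{path}: ADC code inconsistent with voltage at data row {row} "
                f"(|error| {err.max():.6f} V > half LSB {0.5 * lsb:.6f} V)"
            )
    return trace


def write_trace(trace: SignalTrace, path: str | os.PathLike) -> None:
    """Write a trace CSV with header ``time_s,voltage_v[,adc_code]``."""
    if len(trace) < 2:
        raise TraceFormatError("refusing to write a trace with fewer than 2 samples")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_meta(fh, trace.meta)
        codes = trace.meta.get("adc_codes") if trace.meta else None
        header = "time_s,voltage_v" + (",adc_code" if codes is not None else "")
        fh.write(header + "\n")
        for i in range(len(trace)):
            row = (
                f"{trace.times[i]:.{TIME_DECIMALS}f},"
                f"{trace.voltages[i]:.{VOLTAGE_DECIMALS}f}"
            )
            if codes is not None:
                row += f",{int(codes[i])}"  # type: ignore[index]
            fh.write(row + "\n")


def read_rssi_table(path: str | os.PathLike) -> list[RssiSample]:
    """Read a ``distance_m,rssi_dbm`` table; output sorted by distance.

    Duplicate distances are kept — they are replicate measurements.
    """
    frame, _ = _read_csv_with_meta(path)
    for col in ("distance_m", "rssi_dbm"):
        if col not in frame.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r}; available: {list(frame.columns)}"
            )
    samples = [
        RssiSample(float(d), float(r))
        for d, r in zip(frame["distance_m"], frame["rssi_dbm"])
    ]
    return sorted(samples, key=lambda s: s.distance_m)


def write_rssi_table(samples: Sequence[RssiSample], path: str | os.PathLike) -> None:
    """Write RSSI samples as a ``distance_m,rssi_dbm`` CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("distance_m,rssi_dbm\n")
        for s in samples:
            fh.write(f"{s.distance_m:.{VOLTAGE_DECIMALS}f},{s.rssi_dbm:.{VOLTAGE_DECIMALS}f}\n")


def read_segments(path: str | os.PathLike) -> pd.DataFrame:
    """Read a segments CSV (``label,t_start_s,t_end_s[,feature columns]``)."""
    frame, _ = _read_csv_with_meta(path)
    for col in ("label", "t_start_s", "t_end_s"):
        if col not in frame.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r}; available: {list(frame.columns)}"
            )
    return frame


def write_segments(segments, path: str | os.PathLike) -> None:
    """Write behavior segments (truth or classified) as CSV.

    Accepts any iterable of objects with ``label``, ``t_start_s``, ``t_end_s``
    and optionally a ``features`` attribute carrying the window aggregate.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label,t_start_s,t_end_s,frequency_hz,amplitude_v,dvdt_amp\n")
        for seg in segments:
            label = getattr(seg.label, "name", seg.label)
            feats = getattr(seg, "features", None)
            if feats is None:
                tail = ",,"
            else:
                tail = (
                    f"{feats.frequency_hz:.{VOLTAGE_DECIMALS}f},"
                    f"{feats.amplitude_v:.{VOLTAGE_DECIMALS}f},"
                    f"{feats.dvdt_amp:.{VOLTAGE_DECIMALS}f}"
                )
            fh.write(
                f"{label},{seg.t_start_s:.{VOLTAGE_DECIMALS}f},"
                f"{seg.t_end_s:.{VOLTAGE_DECIMALS}f},{tail}\n"
            )
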