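"""Piecewise-constant voltage-clamp protocols.

A protocol is an ordered list of (duration, voltage) segments, in seconds
and volts.  ``voltage_at`` uses the half-open convention [start, end): at a
step edge the later segment's voltage applies, so V(t) is single-valued.

The exact staircase protocol used for rapid hERG characterisation is
published only graphically, so :func:`build_default_staircase` ships a
documented staircase-style approximation satisfying the study's printed
constraints (500 ms core steps, voltages within [-0.12, 0.06] V, total
duration 15.4 s).  For fidelity work supply the published protocol via CSV.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolParseError

#: Default sanity window for segment voltages, volts.
VOLTAGE_WINDOW = (-0.15, 0.10)

PROTOCOL_CSV_HEADER = ("duration_s", "voltage_V")


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered piecewise-constant voltage command.

    Parameters
    ----------
    segments
        Sequence of ``(duration_s, voltage_V)`` pairs; every duration must
        be strictly positive.
    name
        Free-form label.
    voltage_window
        Sanity bounds (lo, hi) in volts that every segment voltage must
        respect.
    """

    segments: tuple[tuple[float, float], ...]
    name: str = "unnamed"
    voltage_window: tuple[float, float] = VOLTAGE_WINDOW

    def __post_init__(self):
        segs = tuple((float(d), float(v)) for d, v in self.segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        lo, hi = self.voltage_window
        for i, (d, v) in enumerate(segs):
            if not d > 0:
                raise ValueError(f"segment {i}: duration must be > 0, got {d}")
            if not (lo <= v <= hi):
                raise ValueError(
                    f"segment {i}: voltage {v} V outside sanity window [{lo}, {hi}] V"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        """Sum of segment durations, seconds."""
        return float(sum(d for d, _ in self.segments))

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for d, _ in self.segments])

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for _, v in self.segments])

    @property
    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time (length n+1)."""
        return np.concatenate([[0.0], np.cumsum(self.durations)])

    def voltage_at(self, t: float) -> float:
        """Voltage of the segment containing time ``t`` (half-open bins)."""
        total = self.total_duration
        if not (0.0 <= t < total):
            raise ValueError(f"t={t} outside [0, {total})")
        idx = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        idx = min(idx, len(self.segments) - 1)
        return self.segments[idx][1]

    def voltage_series(self, times: np.ndarray) -> np.ndarray:
        """Vectorized ``voltage_at`` for an array of times."""
        times = np.asarray(times, dtype=float)
        total = self.total_duration
        if times.size and (times.min() < 0 or times.max() >= total):
            raise ValueError("times outside [0, total_duration)")
        idx = np.searchsorted(self.boundaries, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        return self.voltages[idx]


def voltage_at(protocol: VoltageProtocol, t: float) -> float:
    return protocol.voltage_at(t)


def build_default_staircase() -> VoltageProtocol:
    """Deterministic staircase-style protocol.

    Layout: 1.0 s holding at -80 mV; a 0.5 s activation probe at +40 mV and
    0.5 s return to holding; a 12 s core of twenty-four 500 ms steps
    zig-zagging up and then back down across [-120, +60] mV; a 0.5 s
    deactivation probe at -120 mV; 0.9 s trailing holding.  Total 15.4 s.

    This is an in-house approximation of the published staircase (which is
    available only as a figure); it honours the printed constraints —
    500 ms core steps, voltages confined to [-0.12, 0.06] V, 15.4 s total.
    """
    mv = 1e-3
    core_levels_mv = [
        -40, -100, -20, -80, 0, -60, 20, -40, 40, -20, 60, 0,
        40, -20, 20, -40, 0, -60, -20, -80, -40, -100, -60, -120,
    ]
    segments: list[tuple[float, float]] = [(1.0, -80 * mv)]
    segments.append((0.5, 40 * mv))
    segments.append((0.5, -80 * mv))
    segments.extend((0.5, v * mv) for v in core_levels_mv)
    segments.append((0.5, -120 * mv))
    segments.append((0.9, -80 * mv))
    return VoltageProtocol(tuple(segments), name="staircase-approx")


def read_protocol_csv(path) -> VoltageProtocol:
    """Read a protocol from CSV with header ``duration_s,voltage_V``."""
    with open(path, "r", newline="") as fh:
        return _read_protocol(fh, name=str(path))


def _read_protocol(fh, name: str) -> VoltageProtocol:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ProtocolParseError("empty protocol file") from None
    if [h.strip() for h in header] != list(PROTOCOL_CSV_HEADER):
        raise ProtocolParseError(
            f"expected header {','.join(PROTOCOL_CSV_HEADER)!r}, got {','.join(header)!r}",
            line=1,
        )
    segments = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 2:
            raise ProtocolParseError(f"expected 2 columns, got {len(row)}", line=lineno)
        try:
            d, v = float(row[0]), float(row[1])
        except ValueError:
            raise ProtocolParseError(f"non-numeric row {row!r}", line=lineno) from None
        if not d > 0:
            raise ProtocolParseError(f"non-positive duration {d}", line=lineno)
        segments.append((d, v))
    if not segments:
        raise ProtocolParseError("protocol file has no segment rows")
    return VoltageProtocol(tuple(segments), name=name)


def write_protocol_csv(protocol: VoltageProtocol, path) -> None:
    """Write a protocol to CSV; output is byte-stable (repr-based floats)."""
    buf = io.StringIO()
    buf.write(",".join(PROTOCOL_CSV_HEADER) + "\n")
    for d, v in protocol.segments:
        buf.write(f"{d!r},{v!r}\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())
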