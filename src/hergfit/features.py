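"""Time–frequency featurization of current traces.

A trace is turned into a log-compressed magnitude spectrogram by a
Short-Time Fourier Transform with centered framing: the signal is
reflect-padded by ``n_fft // 2`` on each side, a periodic Hann window of
length ``win`` (zero-padded centrally to ``n_fft``) slides with the given
hop, and a one-sided FFT is taken per frame.  With the defaults
(n_fft=256, hop=12, win=48) a 1,540-sample trace yields a 129x129 grid:
rows = n_fft/2 + 1 = 129, cols = floor(n/hop) + 1 = 129.

Before the STFT the trace is divided by a fixed global current scale
(10^4 pA by default) rather than a per-trace maximum, so absolute
amplitude — the main cue for the conductance g_Kr — survives into the
features.  log1p compression keeps silent regions at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft
from scipy.signal.windows import hann

from .dataset import CurrentTrace

#: fixed global current scale, pA, applied before the STFT
DEFAULT_TRACE_SCALE = 1e4


@dataclass(frozen=True)
class StftParams:
    n_fft: int = 256
    hop: int = 12
    win: int = 48

    def __post_init__(self):
        if not (self.n_fft >= self.win >= 1 and self.hop >= 1):
            raise ValueError("need n_fft >= win >= 1 and hop >= 1")


DEFAULT_STFT = StftParams()


@dataclass(frozen=True)
class Spectrogram:
    """Non-negative time–frequency grid (frequency bins x time frames)."""

    grid: np.ndarray
    stft_params: StftParams | None = None

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("grid entries must be finite and >= 0")
        object.__setattr__(self, "grid", g)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.grid.shape


def _frames(x: np.ndarray, params: StftParams) -> np.ndarray:
    """Centered frames of length n_fft: frame k spans k*hop .. k*hop+n_fft
    of the reflect-padded signal, so its center sits at sample k*hop."""
    pad = params.n_fft // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = x.size // params.hop + 1
    idx = np.arange(params.n_fft)[None, :] + params.hop * np.arange(n_frames)[:, None]
    return xp[idx]


def _window(params: StftParams) -> np.ndarray:
    # periodic Hann of length win, zero-padded centrally to n_fft
    w = hann(params.win, sym=False)
    out = np.zeros(params.n_fft)
    start = (params.n_fft - params.win) // 2
    out[start:start + params.win] = w
    return out


def stft_spectrogram(
    trace: CurrentTrace | np.ndarray,
    params: StftParams = DEFAULT_STFT,
    trace_scale: float = DEFAULT_TRACE_SCALE,
    compression: str = "log1p",
) -> Spectrogram:
    """Magnitude spectrogram of a current trace.

    Output shape is ``(n_fft // 2 + 1, floor(len / hop) + 1)``.
    ``compression`` is ``"log1p"`` (default) or ``"none"`` (raw magnitude).
    """
    x = trace.values if isinstance(trace, CurrentTrace) else np.asarray(trace, float)
    if x.size < params.win:
        raise ValueError(f"trace length {x.size} shorter than window {params.win}")
    x = x / trace_scale
    frames = _frames(x, params) * _window(params)
    mag = np.abs(rfft(frames, n=params.n_fft, axis=1)).T  # (freq, time)
    if compression == "log1p":
        mag = np.log1p(mag)
    elif compression != "none":
        raise ValueError(f"unknown compression {compression!r}")
    return Spectrogram(grid=mag, stft_params=params)


def resize_spectrogram(spec: Spectrogram, rows: int, cols: int) -> Spectrogram:
    """Bilinear (align-corners) resize to (rows, cols).

    Separable linear interpolation on the corner-aligned grid: resizing to
    the input shape is the exact identity and constants are preserved.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    return Spectrogram(grid=_resize(spec.grid, rows, cols), stft_params=spec.stft_params)


def _resize(grid: np.ndarray, rows: int, cols: int) -> np.ndarray:
    r0, c0 = grid.shape
    if (rows, cols) == (r0, c0):
        return grid.copy()
    ri = np.linspace(0.0, r0 - 1.0, rows)
    ci = np.linspace(0.0, c0 - 1.0, cols)
    tmp = np.empty((rows, c0))
    src_r = np.arange(r0, dtype=float)
    for j in range(c0):
        tmp[:, j] = np.interp(ri, src_r, grid[:, j])
    out = np.empty((rows, cols))
    src_c = np.arange(c0, dtype=float)
    for i in range(rows):
        out[i] = np.interp(ci, src_c, tmp[i])
    return out


def trace_to_input(
    trace: CurrentTrace | np.ndarray,
    resolution: tuple[int, int],
    params: StftParams = DEFAULT_STFT,
    trace_scale: float = DEFAULT_TRACE_SCALE,
) -> Spectrogram:
    """STFT then resize — the standard front-end for the regressor."""
    spec = stft_spectrogram(trace, params=params, trace_scale=trace_scale)
    return resize_spectrogram(spec, *resolution)
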