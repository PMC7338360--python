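"""Shared numeric primitives: moving averages and histogram-mode estimation.

The temporal moving average is the workhorse of the event-detection chain.  It
is centred, with a shrinking window at the boundaries so the output length
equals the input length; ``edge_margin`` tells callers how many frames at each
end were computed from a partial window.
"""

from __future__ import annotations

import numpy as np


def window_frames(window_s: float, frame_rate: float) -> int:
    """Filter length in frames: round(window * rate), at least 1."""
    L = int(round(window_s * frame_rate))
    if L < 1:
        raise ValueError(
            f"window of {window_s} s is shorter than one frame at "
            f"{frame_rate} Hz")
    return L


def moving_average(x: np.ndarray, length: int, axis: int = 0) -> np.ndarray:
    """Centred moving average with a shrinking window at the edges.

    For window length ``L`` the interior sample ``t`` averages
    ``x[t - (L-1)//2 : t + L//2 + 1]``; near the boundaries the window is
    clipped to the array and the divisor shrinks accordingly, preserving the
    output length.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    x = np.asarray(x)
    if length == 1:
        return x.astype(np.result_type(x.dtype, np.float32), copy=True)
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    hl = (length - 1) // 2
    hr = length // 2
    dtype = np.result_type(x.dtype, np.float32)
    t = np.arange(n)
    lo = np.maximum(t - hl, 0)
    hi = np.minimum(t + hr + 1, n)
    counts = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    out = np.empty(x.shape, dtype=dtype)
    # cumulative sums run in float64 (precision over long movies) but in
    # spatial chunks so the temporary never rivals the movie itself
    flat = x.reshape(n, -1)
    oflat = out.reshape(n, -1)
    npix = flat.shape[1]
    step = max(1, min(npix, int(2e7) // max(n, 1)))
    for j in range(0, npix, step):
        cs = np.zeros((n + 1, min(step, npix - j)), dtype=np.float64)
        np.cumsum(flat[:, j:j + step], axis=0, out=cs[1:])
        oflat[:, j:j + step] = (cs[hi] - cs[lo]) / counts.reshape(-1, 1)
    return np.moveaxis(out, 0, axis)


def edge_margin(length: int) -> tuple[int, int]:
    """Number of partial-window samples at the (start, end) of the output."""
    return (length - 1) // 2, length // 2


def histogram_mode(traces: np.ndarray, n_bins: int = 100,
                   prange: tuple[float, float] = (0.1, 99.9)) -> np.ndarray:
    """Per-row histogram mode of ``traces`` (rows = pixels, columns = time).

    Each row is binned into ``n_bins`` equal bins spanning its
    ``prange`` percentile range; the mode is the centre of the fullest bin
    (earliest bin on ties).  Degenerate rows (zero range) return their value.
    """
    traces = np.asarray(traces)
    if traces.ndim == 1:
        return histogram_mode(traces[None, :], n_bins, prange)[0]
    n_rows, n_t = traces.shape
    out = np.empty(n_rows, dtype=np.float64)
    step = max(1, int(2e7) // max(n_t, 1))  # bound temporary size
    for j in range(0, n_rows, step):
        chunk = np.asarray(traces[j:j + step], dtype=np.float64)
        lo, hi = np.percentile(chunk, prange, axis=1)
        span = hi - lo
        degenerate = span <= 0
        span_safe = np.where(degenerate, 1.0, span)
        idx = np.floor((chunk - lo[:, None]) / span_safe[:, None] * n_bins)
        idx = np.clip(idx, 0, n_bins - 1).astype(np.intp)
        idx += np.arange(chunk.shape[0])[:, None] * n_bins
        counts = np.bincount(idx.ravel(),
                             minlength=chunk.shape[0] * n_bins)
        best = np.argmax(counts.reshape(chunk.shape[0], n_bins), axis=1)
        mode = lo + (best + 0.5) * span_safe / n_bins
        mode[degenerate] = lo[degenerate]
        out[j:j + step] = mode
    return out
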