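"""Transition-locked Ca2+ dynamics.

ROA frequency traces are smoothed with a causal kernel
``k(t) = t * exp(-t / tau)`` (tau = 0.25 s, unit area): unlike a symmetric
Gaussian it has no response before an impulse, so onset estimates are not
skewed to earlier values.  Traces are collected in a window of -15 to +15 s
around each transition, z-scored against the baseline portion (-15 to -5 s),
and the Ca2+ onset is the first threshold crossing (2.5 baseline SDs,
scanned from the end of the baseline window); peaks are the window maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["AlignedTraceMatrix", "OnsetEstimate", "smooth_causal",
           "align_and_zscore", "estimate_onset", "estimate_peak",
           "astro_neuron_correlation"]


@dataclass
class AlignedTraceMatrix:
    """Transition-aligned, baseline-z-scored traces (rows = transitions)."""

    z: np.ndarray
    times_s: np.ndarray          # relative to the transition
    valid: np.ndarray            # rows with non-degenerate baseline
    baseline_end_s: float = -5.0
    n_dropped_incomplete: int = 0

    @property
    def n_transitions(self) -> int:
        return self.z.shape[0]


@dataclass
class OnsetEstimate:
    onset_s: float
    detected: bool


def causal_kernel(tau_s: float, dt_s: float) -> np.ndarray:
    """Discrete ``t * exp(-t/tau)`` kernel, normalised to unit sum."""
    if tau_s <= 0:
        raise ValueError("tau must be > 0")
    t = np.arange(0.0, 10.0 * tau_s + dt_s, dt_s)
    k = t * np.exp(-t / tau_s)
    return k / k.sum()


def smooth_causal(trace: np.ndarray, frame_rate: float,
                  tau_s: float = 0.25) -> np.ndarray:
    """Causal convolution with the unit-area ``t*exp(-t/tau)`` kernel.

    The output at frame ``n`` depends only on frames ``<= n`` (the kernel's
    first tap is zero, so an impulse produces no response before itself and
    peaks one ``tau`` later); a constant input is returned unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    k = causal_kernel(tau_s, 1.0 / frame_rate)
    return np.convolve(trace, k, mode="full")[:trace.size]


def align_and_zscore(trace: np.ndarray, frame_rate: float,
                     transition_times_s: np.ndarray,
                     window_s: tuple[float, float] = (-15.0, 15.0),
                     baseline_s: tuple[float, float] = (-15.0, -5.0)
                     ) -> AlignedTraceMatrix:
    """Collect per-transition windows and z-score each by its baseline.

    Transitions whose window extends past the recording are dropped (count
    recorded); rows with zero baseline SD are kept but flagged invalid and
    excluded from onset statistics.
    """
    trace = np.asarray(trace, dtype=float)
    lo = int(round(window_s[0] * frame_rate))
    hi = int(round(window_s[1] * frame_rate))
    offsets = np.arange(lo, hi + 1)
    times = offsets / frame_rate
    rows, dropped = [], 0
    for t in np.atleast_1d(transition_times_s):
        c = int(round(t * frame_rate))
        if c + lo < 0 or c + hi >= trace.size:
            dropped += 1
            continue
        rows.append(trace[c + offsets])
    z = np.array(rows, dtype=float).reshape(len(rows), offsets.size)
    base_cols = (times >= baseline_s[0]) & (times <= baseline_s[1])
    mu = z[:, base_cols].mean(axis=1, keepdims=True)
    sd = z[:, base_cols].std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (z - mu) / sd_safe
    return AlignedTraceMatrix(z=z, times_s=times, valid=valid,
                              baseline_end_s=baseline_s[1],
                              n_dropped_incomplete=dropped)


def estimate_onset(aligned: AlignedTraceMatrix, threshold: float = 2.5,
                   scan: str = "excursion") -> list[OnsetEstimate]:
    """Onset: where the trace first crossed ``threshold`` baseline SDs.

    Only times after the baseline window are scanned.  With
    ``scan='excursion'`` (default) the onset is the threshold crossing that
    starts the suprathreshold excursion containing the window peak — i.e.
    where the response itself crossed the threshold; isolated baseline
    noise crossings ahead of the response are not mistaken for onsets.
    ``scan='forward'`` returns the very first suprathreshold sample
    instead.  Rows with degenerate baselines report ``detected=False``.
    """
    if scan not in ("excursion", "forward"):
        raise ValueError("scan must be 'excursion' or 'forward'")
    start = int(np.argmax(aligned.times_s >= aligned.baseline_end_s))
    out = []
    for row, ok in zip(aligned.z, aligned.valid):
        if not ok:
            out.append(OnsetEstimate(float("nan"), False))
            continue
        seg = row[start:]
        above = seg > threshold
        if not above.any():
            out.append(OnsetEstimate(float("nan"), False))
            continue
        if scan == "forward":
            i = int(np.argmax(above))
        else:
            i = int(np.argmax(seg))          # window peak
            while i > 0 and above[i - 1]:    # back to excursion start
                i -= 1
        out.append(OnsetEstimate(float(aligned.times_s[start + i]), True))
    return out


def estimate_peak(aligned: AlignedTraceMatrix) -> np.ndarray:
    """Per-row maximum over the full window (z units)."""
    return aligned.z.max(axis=1)


def astro_neuron_correlation(astro: np.ndarray, neuron: np.ndarray,
                             frame_rate: float, smooth_sigma_s: float = 0.25,
                             max_lag_s: float = 2.0
                             ) -> tuple[float, float]:
    """Maximum Pearson cross-correlation between the two smoothed traces.

    Returns ``(max_correlation, lag_s)``; positive lag means the neuronal
    trace leads.  Both traces are Gaussian-smoothed (sigma 0.25 s) first.
    Constant traces yield ``(nan, nan)``.
    """
    a = np.asarray(astro, dtype=float)
    n = np.asarray(neuron, dtype=float)
    if a.shape != n.shape:
        raise ValueError("traces must have equal length")
    if a.size < 100:
        raise ValueError("need at least 100 samples")
    if a.std() == 0 or n.std() == 0:
        return float("nan"), float("nan")
    sig = smooth_sigma_s * frame_rate
    a = gaussian_filter1d(a, sig)
    n = gaussian_filter1d(n, sig)
    max_lag = int(round(max_lag_s * frame_rate))
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], n[:n.size - lag]
        else:
            x, y = a[:lag], n[-lag:]
        if x.std() == 0 or y.std() == 0:
            return float("nan"), float("nan")
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag / frame_rate
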