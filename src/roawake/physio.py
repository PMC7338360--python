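"""Sleep-wake scoring, transitions, microarousals, band power and spindles.

Scoring follows standard rodent criteria on ECoG/EMG plus video motion:

* wakefulness sub-states from motion traces — above-threshold wheel motion is
  locomotion (which subsumes whisking), above-threshold snout motion alone is
  whisking, neither is quiet wakefulness;
* NREM sleep: high-amplitude delta (0.5-4 Hz) ECoG with low EMG;
* IS (intermediate) sleep: increased sigma (10-16 Hz) and theta (5-9 Hz)
  power with decreasing delta;
* REM sleep: theta/delta power ratio > 0.5 with low EMG.

Scoring runs on 1 s epochs with 3-epoch majority smoothing.  "High"/"low"
thresholds are multiples of per-recording reference statistics so they are
scale-free; all are exposed in :class:`ScoringParams`.  Sleep episodes of
30 s or less are flagged as excluded from state analyses.

Sleep spindles are detected on the (normalised) ECoG by 10-16 Hz zero-phase
second-order Butterworth bandpass filtering, Hilbert-transform envelope,
Gaussian smoothing (sigma 0.2 s) and peak picking; candidate peaks whose
width at the threshold level falls outside [0.5, 5] s are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import SLEEP_STATES, Hypnogram

#: Canonical ECoG bands (Hz).  The sigma band is 10-16 Hz by default; some
#: descriptions use 9-16 Hz, so the bounds are plain data and overridable.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 9.0),
    "sigma": (10.0, 16.0),
    "total": (0.5, 30.0),
}


@dataclass
class PhysioRecording:
    """ECoG + EMG sampled at a common rate (>= 100 Hz)."""

    ecog: np.ndarray
    emg: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.ecog = np.asarray(self.ecog, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.ecog.shape != self.emg.shape:
            raise ValueError("ecog and emg must have equal length")
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")

    @property
    def duration_s(self) -> float:
        return self.ecog.size / self.sampling_rate


@dataclass
class MicroarousalEvent:
    start_s: float
    duration_s: float
    host_episode: int  # index of the NREM episode in the hypnogram


@dataclass
class SpindleEvent:
    start_s: float
    end_s: float
    peak_time_s: float
    peak_amplitude: float

    @property
    def width_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Transition:
    from_state: str
    to_state: str
    time_s: float
    awakening: bool
    refined: bool = False


@dataclass
class ScoringParams:
    """Thresholds of the rule-based scorer (multiples of reference stats)."""

    epoch_s: float = 1.0
    smooth_epochs: int = 3
    #: band powers are averaged over this many centred epochs before the
    #: ratio rules: one-epoch spectral estimates of the delta band are too
    #: noisy to classify on directly.
    power_smooth_epochs: int = 5
    #: EMG is "high" above emg_factor x the 20th percentile of epoch RMS.
    emg_factor: float = 2.5
    emg_threshold: float | None = None
    #: motion is "above threshold" beyond median + motion_mad_factor x MAD.
    motion_mad_factor: float = 10.0
    theta_delta_rem: float = 0.5
    #: IS requires sigma elevated against BOTH delta and theta; REM is
    #: ruled out of IS by its near-absent sigma band
    sigma_delta_is: float = 0.15
    sigma_theta_is: float = 0.5
    min_sleep_episode_s: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be > 0")
        if self.smooth_epochs < 1 or self.smooth_epochs % 2 == 0:
            raise ValueError("smooth_epochs must be a positive odd integer")
        for name in ("emg_factor", "motion_mad_factor", "theta_delta_rem",
                     "sigma_delta_is", "sigma_theta_is"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ------------------------------------------------------------- band power

def band_power(ecog: np.ndarray, sampling_rate: float,
               band: tuple[float, float], window_s: float,
               step_s: float | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Welch band-integrated power in sliding windows.

    Returns ``(window_center_times_s, power)``.  ``step_s`` defaults to the
    window length (non-overlapping windows).
    """
    lo, hi = band
    if hi > sampling_rate / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist "
                         f"({sampling_rate / 2} Hz)")
    ecog = np.asarray(ecog, dtype=float)
    win = int(round(window_s * sampling_rate))
    step = win if step_s is None else int(round(step_s * sampling_rate))
    if win < 8 or step < 1:
        raise ValueError("window too short")
    n_win = 1 + (ecog.size - win) // step
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    idx = np.arange(win)[None, :] + step * np.arange(n_win)[:, None]
    segs = ecog[idx]
    freqs, psd = signal.welch(segs, fs=sampling_rate,
                              nperseg=min(win, 1024), axis=1)
    power = _integrate_band(freqs, psd, lo, hi)
    times = (np.arange(n_win) * step + win / 2) / sampling_rate
    return times, power


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, lo: float,
                    hi: float) -> np.ndarray:
    """Integrate the PSD over [lo, hi], weighting partial edge bins by
    their overlap so band power is proportional to bandwidth on a flat
    spectrum."""
    df = freqs[1] - freqs[0]
    left = np.maximum(freqs - df / 2, lo)
    right = np.minimum(freqs + df / 2, hi)
    w = np.clip(right - left, 0.0, None)
    return psd @ w


def epoch_band_powers(ecog: np.ndarray, sampling_rate: float,
                      epoch_s: float,
                      bands: dict[str, tuple[float, float]] | None = None
                      ) -> dict[str, np.ndarray]:
    """Band-integrated power per non-overlapping epoch for several bands."""
    bands = bands or BANDS
    win = int(round(epoch_s * sampling_rate))
    n_ep = ecog.size // win
    segs = np.asarray(ecog[:n_ep * win], dtype=float).reshape(n_ep, win)
    freqs, psd = signal.welch(segs, fs=sampling_rate, nperseg=win, axis=1)
    return {name: _integrate_band(freqs, psd, lo, hi)
            for name, (lo, hi) in bands.items()}


def normalize_power(powers: dict[str, np.ndarray], hypnogram: Hypnogram,
                    epoch_s: float,
                    reference: float | None = None
                    ) -> tuple[dict[str, np.ndarray], float]:
    """Divide all band powers by the NREM-average total (0.5-30 Hz) power.

    Returns the normalised traces and the reference scalar.  Without NREM in
    the hypnogram an explicit ``reference`` value must be supplied.
    """
    if reference is None:
        n_ep = next(iter(powers.values())).size
        times = (np.arange(n_ep) + 0.5) * epoch_s
        in_nrem = hypnogram.labels(times) == "NREM"
        if not in_nrem.any():
            raise ValueError("no NREM epochs in the hypnogram; pass an "
                             "explicit reference power")
        reference = float(powers["total"][in_nrem].mean())
    if reference <= 0:
        raise ValueError("reference power must be > 0")
    return {k: v / reference for k, v in powers.items()}, reference


def normalize_ecog(ecog: np.ndarray, sampling_rate: float,
                   hypnogram: Hypnogram) -> np.ndarray:
    """Scale the raw trace by sqrt(NREM-average total power)."""
    powers = epoch_band_powers(ecog, sampling_rate, 1.0,
                               {"total": BANDS["total"]})
    _, ref = normalize_power(powers, hypnogram, 1.0)
    return np.asarray(ecog, dtype=float) / np.sqrt(ref)


# ----------------------------------------------------------------- scoring

def motion_threshold(trace: np.ndarray, mad_factor: float = 10.0) -> float:
    """Robust burst threshold: median + mad_factor x scaled MAD."""
    med = float(np.median(trace))
    mad = float(np.median(np.abs(trace - med))) * 1.4826
    return med + mad_factor * mad


def _epoch_reduce(trace: np.ndarray, fs: float, epoch_s: float, n_ep: int,
                  fn) -> np.ndarray:
    win = int(round(epoch_s * fs))
    m = min(n_ep, trace.size // win)
    out = fn(trace[:m * win].reshape(m, win), axis=1)
    if m < n_ep:  # pad with the last value if streams differ by < 1 epoch
        out = np.concatenate([out, np.repeat(out[-1], n_ep - m)])
    return out


def score_wake(wheel: np.ndarray, snout: np.ndarray,
               wheel_threshold: float, snout_threshold: float) -> np.ndarray:
    """Per-sample wake sub-state labels from motion traces.

    Locomotion takes precedence over whisking (locomotion comprises both
    movement and whisking); neither signal above threshold is quiet.
    """
    wheel = np.asarray(wheel, dtype=float)
    snout = np.asarray(snout, dtype=float)
    if wheel.shape != snout.shape:
        raise ValueError("wheel and snout traces must be time-aligned")
    labels = np.full(wheel.shape, "quiet", dtype=object)
    labels[snout > snout_threshold] = "whisking"
    labels[wheel > wheel_threshold] = "locomotion"
    return labels


def _majority_smooth(labels: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or labels.size < k:
        return labels
    half = k // 2
    out = labels.copy()
    for i in range(half, labels.size - half):
        window = labels[i - half:i + half + 1]
        vals, counts = np.unique(window, return_counts=True)
        best = counts.max()
        if best > half and labels[i] not in vals[counts == best]:
            out[i] = vals[np.argmax(counts)]
    return out


def score_session(recording: PhysioRecording,
                  wheel: np.ndarray | None = None,
                  snout: np.ndarray | None = None,
                  motion_sampling_rate: float | None = None,
                  params: ScoringParams | None = None) -> Hypnogram:
    """Rule-based six-state hypnogram from ECoG, EMG and motion traces."""
    p = params or ScoringParams()
    fs = recording.sampling_rate
    powers = epoch_band_powers(recording.ecog, fs, p.epoch_s)
    if p.power_smooth_epochs > 1:
        from ._filters import moving_average
        powers = {k: moving_average(v, p.power_smooth_epochs)
                  for k, v in powers.items()}
    n_ep = powers["delta"].size
    emg_rms = _epoch_reduce(recording.emg, fs, p.epoch_s, n_ep,
                            lambda a, axis: np.sqrt(np.mean(a ** 2,
                                                            axis=axis)))
    emg_thr = p.emg_threshold if p.emg_threshold is not None else \
        p.emg_factor * float(np.percentile(emg_rms, 20))
    emg_high = emg_rms > emg_thr

    if wheel is not None and snout is not None:
        fm = motion_sampling_rate or fs
        wheel_ep = _epoch_reduce(np.asarray(wheel, float), fm, p.epoch_s,
                                 n_ep, np.mean)
        snout_ep = _epoch_reduce(np.asarray(snout, float), fm, p.epoch_s,
                                 n_ep, np.mean)
        w_thr = motion_threshold(wheel_ep, p.motion_mad_factor)
        s_thr = motion_threshold(snout_ep, p.motion_mad_factor)
        wake_labels = score_wake(wheel_ep, snout_ep, w_thr, s_thr)
        moving = (wheel_ep > w_thr) | (snout_ep > s_thr)
    else:
        wake_labels = np.full(n_ep, "quiet", dtype=object)
        moving = np.zeros(n_ep, dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        theta_delta = powers["theta"] / powers["delta"]
        sigma_delta = powers["sigma"] / powers["delta"]
        sigma_theta = powers["sigma"] / powers["theta"]

    labels = np.empty(n_ep, dtype=object)
    wake = moving | emg_high
    labels[wake] = wake_labels[wake]
    asleep = ~wake
    rem = asleep & (theta_delta > p.theta_delta_rem) & \
        (sigma_theta < p.sigma_theta_is)
    is_ = asleep & ~rem & (sigma_delta > p.sigma_delta_is) & \
        (sigma_theta > p.sigma_theta_is)
    nrem = asleep & ~rem & ~is_
    labels[rem], labels[is_], labels[nrem] = "REM", "IS", "NREM"
    labels = _majority_smooth(labels, p.smooth_epochs)
    return Hypnogram.from_labels(labels, p.epoch_s)


# ------------------------------------------------- microarousals/transitions

def _threshold_intervals(trace: np.ndarray, fs: float, threshold: float
                         ) -> list[tuple[float, float]]:
    above = np.asarray(trace) > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def detect_microarousals(snout: np.ndarray, motion_sampling_rate: float,
                         hypnogram: Hypnogram,
                         threshold: float | None = None,
                         min_duration_s: float = 0.3,
                         max_duration_s: float = 3.0
                         ) -> list[MicroarousalEvent]:
    """Brief (0.3 s <= d < 3 s) above-threshold snout bursts in NREM."""
    if threshold is None:
        threshold = motion_threshold(np.asarray(snout, float))
    intervals = _threshold_intervals(snout, motion_sampling_rate, threshold)
    nrem = [(i, ep) for i, ep in enumerate(hypnogram.episodes)
            if ep.state == "NREM"]
    out = []
    for s, e in intervals:
        dur = e - s
        if not (min_duration_s <= dur < max_duration_s):
            continue
        for i, ep in nrem:
            if ep.start_s <= s and e <= ep.end_s:
                out.append(MicroarousalEvent(s, dur, i))
                break
    return out


def detect_transitions(hypnogram: Hypnogram,
                       ecog: np.ndarray | None = None,
                       sampling_rate: float | None = None,
                       method: str = "desync",
                       search_s: float = 5.0) -> list[Transition]:
    """State-boundary events; sleep-to-wake times optionally refined.

    With ``method='desync'`` and an ECoG trace, awakening onsets are moved to
    the first 1 s window, scanning from ``search_s`` before the scored
    boundary, where delta power (theta power for REM endings) drops below
    50% of the preceding episode's median — an automated surrogate for
    manual desynchronisation marking, flagged via ``refined``.
    """
    if method not in ("hypnogram", "desync"):
        raise ValueError("method must be 'hypnogram' or 'desync'")
    out: list[Transition] = []
    eps = hypnogram.episodes
    for prev, nxt in zip(eps, eps[1:]):
        t = prev.end_s
        awakening = prev.state in SLEEP_STATES and \
            nxt.state not in SLEEP_STATES
        refined = False
        if (awakening and method == "desync" and ecog is not None
                and sampling_rate is not None):
            band = BANDS["theta"] if prev.state == "REM" else BANDS["delta"]
            t_ref = _desync_onset(ecog, sampling_rate, prev.start_s, t,
                                  band, search_s)
            if t_ref is not None:
                t, refined = t_ref, True
        out.append(Transition(prev.state, nxt.state, t, awakening, refined))
    return out


def _desync_onset(ecog: np.ndarray, fs: float, ep_start: float,
                  boundary: float, band: tuple[float, float],
                  search_s: float) -> float | None:
    # 2 s windows: 1 s band-power estimates have too few dof and routinely
    # dip below half their median, false-triggering the rule
    win_s = 2.0
    seg = ecog[int(ep_start * fs):int(boundary * fs)]
    if seg.size < 2 * win_s * fs:
        return None
    _, ref_power = band_power(seg, fs, band, window_s=win_s)
    ref = np.median(ref_power)
    t0 = max(ep_start, boundary - search_s)
    t1 = min(boundary + search_s, ecog.size / fs)
    win = ecog[int(t0 * fs):int(t1 * fs)]
    if win.size < win_s * fs:
        return None
    times, power = band_power(win, fs, band, window_s=win_s, step_s=0.1)
    low = power < 0.3 * ref
    # the low condition must persist: short band-power dips are ordinary
    # fluctuations, sustained collapse marks desynchronisation
    need = max(1, int(round(1.5 / 0.1)))
    run, start = 0, None
    for i, flag in enumerate(low):
        run = run + 1 if flag else 0
        if run >= need:
            start = i - need + 1
            break
    if start is None:
        return None
    # earliest time consistent with the first persistently-low window
    return float(max(t0, t0 + times[start] - win_s / 2))


# ---------------------------------------------------------------- spindles

def detect_spindles(ecog: np.ndarray, sampling_rate: float,
                    peak_threshold: float | None = None,
                    band: tuple[float, float] = (10.0, 16.0),
                    envelope_smooth_s: float = 0.2,
                    min_width_s: float = 0.5,
                    max_width_s: float = 5.0,
                    episodes: list[tuple[float, float]] | None = None
                    ) -> list[SpindleEvent]:
    """Bandpass-Hilbert spindle detection with the width-at-threshold rule.

    ``peak_threshold`` defaults to median + 2.5 robust SDs (scaled MAD) of
    the smoothed envelope: the amplitude criterion is not standardised, and
    a robust scale keeps the spindles themselves from inflating the
    threshold, while staying scale-free for normalised or raw traces.
    Candidates whose envelope width at the threshold level is
    < ``min_width_s`` or > ``max_width_s`` are discarded.

    ``episodes`` restricts both the threshold statistics and the search to
    the given ``(start_s, end_s)`` windows (e.g. scored IS sleep episodes);
    without it the whole trace is used.
    """
    if sampling_rate <= 2 * band[1]:
        raise ValueError("sampling rate too low for the spindle band")
    if peak_threshold is not None and peak_threshold <= 0:
        raise ValueError("peak_threshold must be > 0")
    x = np.asarray(ecog, dtype=float)
    sos = signal.butter(2, band, btype="bandpass", fs=sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(filtered))
    env = gaussian_filter1d(env, sigma=envelope_smooth_s * sampling_rate)
    if episodes is None:
        windows = [(0, env.size)]
    else:
        windows = [(max(int(a * sampling_rate), 0),
                    min(int(b * sampling_rate), env.size))
                   for a, b in episodes]
        windows = [(a, b) for a, b in windows if b > a]
        if not windows:
            return []
    pooled = np.concatenate([env[a:b] for a, b in windows])
    if peak_threshold is not None:
        thr = peak_threshold
    else:
        med = float(np.median(pooled))
        robust_sd = 1.4826 * float(np.median(np.abs(pooled - med)))
        thr = med + 2.5 * robust_sd
    out = []
    for a, b in windows:
        t_off = a / sampling_rate
        for s, e in _threshold_intervals(env[a:b], sampling_rate, thr):
            width = e - s
            if not (min_width_s <= width <= max_width_s):
                continue
            i0 = a + int(s * sampling_rate)
            i1 = max(a + int(e * sampling_rate), i0 + 1)
            peak_i = i0 + int(np.argmax(env[i0:i1]))
            out.append(SpindleEvent(start_s=t_off + s, end_s=t_off + e,
                                    peak_time_s=peak_i / sampling_rate,
                                    peak_amplitude=float(env[peak_i])))
    out.sort(key=lambda sp: sp.start_s)
    return out


def spindle_rate(spindles: list[SpindleEvent], hypnogram: Hypnogram,
                 state: str = "IS") -> float:
    """Spindles per minute within (non-excluded) episodes of ``state``."""
    eps = hypnogram.episodes_of(state)
    total_min = sum(ep.duration_s for ep in eps) / 60.0
    if total_min == 0:
        return float("nan")
    n = sum(any(ep.start_s <= sp.peak_time_s < ep.end_s for ep in eps)
            for sp in spindles)
    return n / total_min
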