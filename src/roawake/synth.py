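"""Ground-truthed synthetic imaging and physiology sessions.

The generator emulates the acquisition the toolbox targets: two-photon
fluorescence movies (30 Hz, 512x512 by default) with state-dependent rates of
Gaussian-blob Ca2+ events on a noisy, slowly drifting baseline, alongside
ECoG (state-dependent band-limited noise with spindle bursts in IS sleep),
EMG tone, and video-motion traces, all consistent with a ground-truth
hypnogram.  Every stream is deterministic given the seed.

Event counts per behavioural state follow a Poisson law with the configured
rate (events per 100 um^2 of vessel-free area per minute).  Events are
isotropic spatial Gaussians with a linear rise (20% of the duration) followed
by an exponential decay; their half-max support is kept clear of the vessel
mask and the image border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import (SLEEP_STATES, STATES, WAKE_STATES, Episode, Hypnogram,
                   MovieStack)

__all__ = ["SimulationConfig", "GroundTruthEvent", "PhysioSignals",
           "SyntheticSession", "generate_movie", "generate_physiology",
           "generate_session", "default_state_schedule"]


def default_state_schedule() -> list[tuple[str, float]]:
    """A compact sleep-wake session: wake bouts then an SWS-REM cycle."""
    return [("quiet", 40.0), ("locomotion", 20.0), ("whisking", 20.0),
            ("quiet", 40.0), ("NREM", 120.0), ("IS", 40.0), ("REM", 60.0),
            ("quiet", 20.0)]


#: ECoG band RMS weights per state (delta, theta, sigma, fast).  Chosen so the
#: scoring definitions hold by construction: NREM delta-dominant; IS with
#: elevated sigma/theta and reduced delta; REM with theta/delta power ratio
#: well above 0.5; wake desynchronised (broadband fast activity).
STATE_ECOG_WEIGHTS: dict[str, dict[str, float]] = {
    **{s: {"delta": 0.3, "theta": 0.4, "sigma": 0.2, "fast": 0.8}
       for s in WAKE_STATES},
    "NREM": {"delta": 2.0, "theta": 0.3, "sigma": 0.2, "fast": 0.2},
    "IS": {"delta": 0.9, "theta": 0.6, "sigma": 0.65, "fast": 0.2},
    "REM": {"delta": 0.5, "theta": 1.0, "sigma": 0.15, "fast": 0.2},
}

GENERATOR_BANDS = {"delta": (0.5, 4.0), "theta": (5.0, 9.0),
                   "sigma": (10.0, 16.0), "fast": (20.0, 80.0)}

#: Nuchal EMG RMS per state: high in active wakefulness, low in sleep,
#: lowest in REM (muscle atonia).
STATE_EMG_RMS: dict[str, float] = {
    "locomotion": 3.0, "whisking": 2.0, "quiet": 1.0,
    "NREM": 0.3, "IS": 0.3, "REM": 0.15,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session.

    Rates are events per 100 um^2 of vessel-free area per minute; the sleep
    rates default to 0.23x the quiet-wake rate (sleep-vs-wake contrast of the
    emulated recordings).  Amplitude is in dF/F0 units; baseline, noise and
    drift are raw intensity units.
    """

    image_shape: tuple[int, int] = (512, 512)
    frame_rate: float = 30.0
    pixel_size: float = 0.8
    state_schedule: list[tuple[str, float]] = field(
        default_factory=default_state_schedule)
    event_rate_per_state: dict[str, float] = field(default_factory=lambda: {
        "locomotion": 2.0, "whisking": 1.5, "quiet": 1.0,
        "NREM": 0.23, "IS": 0.23, "REM": 0.23})
    event_amplitude: float = 0.5
    event_sigma_xy_um: float = 1.5
    event_duration_range_s: tuple[float, float] = (0.5, 2.0)
    baseline_level: float = 100.0
    noise_sigma: float = 5.0
    drift_amplitude: float = 2.0
    drift_period_s: float = 60.0
    vessel_mask_fraction: float = 0.05
    shot_noise: bool = False
    spindle_rate_is_per_min: float = 2.0
    physio_sampling_rate: float = 1000.0
    motion_sampling_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (H, W) with H, W >= 8")
        for name in ("frame_rate", "pixel_size", "event_amplitude",
                     "event_sigma_xy_um", "baseline_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sigma", "drift_amplitude",
                     "spindle_rate_is_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.vessel_mask_fraction < 1:
            raise ValueError("vessel_mask_fraction must be in [0, 1)")
        lo, hi = self.event_duration_range_s
        if lo <= 0 or hi < lo:
            raise ValueError("event_duration_range_s must be 0 < lo <= hi")
        if not self.state_schedule:
            raise ValueError("state_schedule must be non-empty")
        for state, dur in self.state_schedule:
            if state not in STATES:
                raise ValueError(f"unknown state label {state!r} in "
                                 f"state_schedule; expected one of {STATES}")
            if dur <= 0:
                raise ValueError("state_schedule durations must be > 0")
        for state, rate in self.event_rate_per_state.items():
            if state not in STATES:
                raise ValueError(f"unknown state label {state!r} in "
                                 "event_rate_per_state")
            if rate < 0:
                raise ValueError(f"event rate for {state!r} must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.state_schedule))

    def hypnogram(self) -> Hypnogram:
        eps, t = [], 0.0
        for state, dur in self.state_schedule:
            eps.append(Episode(state, t, t + dur))
            t += dur
        hyp = Hypnogram(eps)
        for ep in hyp.episodes:
            if ep.state in SLEEP_STATES and ep.duration_s <= 30.0:
                ep.excluded = True
        return hyp


@dataclass
class GroundTruthEvent:
    start_frame: int
    end_frame: int
    centroid_xy: tuple[float, float]
    footprint_area_um2: float
    peak_amplitude: float
    state: str = ""


@dataclass
class PhysioSignals:
    ecog: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    wheel: np.ndarray
    snout: np.ndarray
    motion_sampling_rate: float
    spindle_truth: list[tuple[float, float]]


@dataclass
class SyntheticSession:
    movie: MovieStack
    truth_events: list[GroundTruthEvent]
    hypnogram_truth: Hypnogram
    physio: PhysioSignals
    vessel_mask: np.ndarray
    config: SimulationConfig


def truth_to_frame(events: list[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.start_frame, e.end_frame, e.centroid_xy[0], e.centroid_xy[1],
          e.footprint_area_um2, e.peak_amplitude, e.state) for e in events],
        columns=["start_frame", "end_frame", "centroid_x", "centroid_y",
                 "footprint_area_um2", "peak_amplitude", "state"])


# ------------------------------------------------------------------- movie

def _vessel_mask(shape: tuple[int, int], fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Random smooth blob raster covering ``fraction`` of the field."""
    if fraction == 0:
        return np.zeros(shape, dtype=bool)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    cut = np.quantile(field_, 1.0 - fraction)
    return field_ > cut


def _temporal_profile(n: int) -> np.ndarray:
    """Linear rise over the first 20% of frames, exponential decay after."""
    n_rise = max(1, int(round(0.2 * n)))
    tau = max(1.0, 0.2 * n)
    prof = np.empty(n)
    prof[:n_rise] = np.arange(1, n_rise + 1) / n_rise
    prof[n_rise:] = np.exp(-(np.arange(n - n_rise) + 1) / tau)
    return prof


def generate_movie(config: SimulationConfig
                   ) -> tuple[MovieStack, list[GroundTruthEvent],
                              np.ndarray]:
    """Synthesise a movie; returns (movie, truth events, vessel mask)."""
    rng = np.random.default_rng(config.seed)
    H, W = config.image_shape
    T = config.n_frames
    vessels = _vessel_mask((H, W), config.vessel_mask_fraction, rng)
    sampled_area = (~vessels).sum() * config.pixel_size ** 2

    sigma_px = config.event_sigma_xy_um / config.pixel_size
    r_half = sigma_px * math.sqrt(2 * math.log(2))
    margin = int(math.ceil(r_half)) + 1
    allowed = ~vessels
    allowed = ndimage.binary_erosion(
        allowed, structure=np.ones((2 * margin + 1, 2 * margin + 1)))
    allowed[:margin] = allowed[-margin:] = False
    allowed[:, :margin] = allowed[:, -margin:] = False
    ay, ax = np.nonzero(allowed)
    if ay.size == 0:
        raise ValueError("no admissible event locations outside the vessel "
                         "mask; reduce vessel_mask_fraction or event size")

    movie = np.zeros((T, H, W), dtype=np.float32)
    movie += config.baseline_level
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(T) / config.frame_rate
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period_s + phase)
        movie += drift[:, None, None].astype(np.float32)

    # precompute the half-max footprint in pixels (same for every event)
    half = int(math.ceil(3 * sigma_px))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    blob = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma_px ** 2)).astype(
        np.float32)
    footprint_px = int((blob > 0.5).sum())
    footprint_um2 = footprint_px * config.pixel_size ** 2

    events: list[GroundTruthEvent] = []
    t0 = 0.0
    dur_lo, dur_hi = config.event_duration_range_s
    for state, seg_dur in config.state_schedule:
        rate = config.event_rate_per_state.get(state, 0.0)
        lam = rate * (sampled_area / 100.0) * (seg_dur / 60.0)
        n_events = rng.poisson(lam) if lam > 0 else 0
        f_lo = int(round(t0 * config.frame_rate))
        f_hi = int(round((t0 + seg_dur) * config.frame_rate))
        for _ in range(n_events):
            start = int(rng.integers(f_lo, max(f_lo + 1, f_hi)))
            dur_frames = max(1, int(round(
                rng.uniform(dur_lo, dur_hi) * config.frame_rate)))
            end = min(start + dur_frames - 1, T - 1)
            j = int(rng.integers(ay.size))
            cy, cx = int(ay[j]), int(ax[j])
            prof = _temporal_profile(end - start + 1)
            amp = config.event_amplitude * config.baseline_level
            y0, y1 = max(cy - half, 0), min(cy + half + 1, H)
            x0, x1 = max(cx - half, 0), min(cx + half + 1, W)
            sub = blob[y0 - (cy - half):y1 - (cy - half),
                       x0 - (cx - half):x1 - (cx - half)]
            patch = (amp * sub)[None] * prof[:, None, None].astype(
                np.float32)
            movie[start:end + 1, y0:y1, x0:x1] += patch
            events.append(GroundTruthEvent(
                start_frame=start, end_frame=end, centroid_xy=(cx, cy),
                footprint_area_um2=footprint_um2,
                peak_amplitude=config.event_amplitude, state=state))
        t0 += seg_dur

    if config.shot_noise:
        movie = rng.poisson(np.clip(movie, 0, None)).astype(np.float32)
    if config.noise_sigma > 0:
        movie += rng.standard_normal(movie.shape, dtype=np.float32) \
            * np.float32(config.noise_sigma)
    events.sort(key=lambda e: e.start_frame)
    stack = MovieStack(movie, config.pixel_size, config.frame_rate)
    return stack, events, vessels


# --------------------------------------------------------------- physiology

def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _state_gain(schedule: list[tuple[str, float]], fs: float, n: int,
                per_state: dict[str, float]) -> np.ndarray:
    gain = np.zeros(n)
    t0 = 0.0
    for state, dur in schedule:
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        gain[i0:min(i1, n)] = per_state[state]
        t0 += dur
    return gain


def generate_physiology(state_schedule: list[tuple[str, float]],
                        spindle_rate_is_per_min: float = 2.0,
                        seed: int = 0, sampling_rate: float = 1000.0,
                        motion_sampling_rate: float = 30.0,
                        spindle_amplitude: float = 6.0,
                        microarousal_rate_nrem_per_min: float = 0.0
                        ) -> PhysioSignals:
    """ECoG/EMG/wheel/snout traces consistent with the state schedule.

    ECoG is a sum of band-limited noises with state-specific RMS weights
    (see ``STATE_ECOG_WEIGHTS``); sleep spindles are Hann-windowed 12-14 Hz
    sinusoid bursts of 0.5-2 s added during IS sleep at a Poisson rate.
    Wheel/snout traces are rectified-noise bursts during locomotion (wheel
    and snout) and whisking (snout only), on a small positive baseline.
    """
    if not state_schedule:
        raise ValueError("state_schedule must be non-empty")
    for state, dur in state_schedule:
        if state not in STATES:
            raise ValueError(f"unknown state label {state!r}")
        if dur <= 0:
            raise ValueError("durations must be > 0")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    duration = sum(d for _, d in state_schedule)
    n = int(round(duration * fs))

    ecog = np.zeros(n)
    for band_name, band in GENERATOR_BANDS.items():
        weights = {s: STATE_ECOG_WEIGHTS[s][band_name] for s in STATES}
        ecog += _state_gain(state_schedule, fs, n, weights) \
            * _band_noise(n, band, fs, rng)

    spindle_truth: list[tuple[float, float]] = []
    t0 = 0.0
    for state, dur in state_schedule:
        if state == "IS" and spindle_rate_is_per_min > 0:
            n_sp = rng.poisson(spindle_rate_is_per_min * dur / 60.0)
            placed: list[tuple[float, float]] = []
            for _ in range(n_sp):
                sp_dur = rng.uniform(0.5, 2.0)
                # spindles are discrete, non-overlapping bursts: resample
                # the start until it is clear of already placed ones
                start = None
                for _try in range(20):
                    cand = rng.uniform(t0, t0 + max(dur - sp_dur, 1e-3))
                    if all(cand > b + 1.0 or cand + sp_dur < a - 1.0
                           for a, b in placed):
                        start = cand
                        break
                if start is None:
                    continue
                placed.append((start, start + sp_dur))
                freq = rng.uniform(12.0, 14.0)
                i0 = int(round(start * fs))
                m = int(round(sp_dur * fs))
                if i0 + m > n:
                    continue
                tt = np.arange(m) / fs
                burst = spindle_amplitude * np.hanning(m) * np.sin(
                    2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
                ecog[i0:i0 + m] += burst
                spindle_truth.append((start, start + sp_dur))
        t0 += dur
    spindle_truth.sort()

    emg = _band_noise(n, (100.0, 1000.0), fs, rng) \
        * _state_gain(state_schedule, fs, n, STATE_EMG_RMS)

    fm = motion_sampling_rate
    nm = int(round(duration * fm))
    base = 0.02
    wheel = base * np.abs(rng.standard_normal(nm))
    snout = base * np.abs(rng.standard_normal(nm))
    loco = _state_gain(state_schedule, fm, nm,
                       {s: float(s == "locomotion") for s in STATES})
    whisk = _state_gain(state_schedule, fm, nm,
                        {s: float(s in ("locomotion", "whisking"))
                         for s in STATES})
    wheel += loco * (0.5 + np.abs(rng.standard_normal(nm)))
    snout += whisk * (0.5 + np.abs(rng.standard_normal(nm)))
    if microarousal_rate_nrem_per_min > 0:
        t0 = 0.0
        for state, dur in state_schedule:
            if state == "NREM":
                for _ in range(rng.poisson(
                        microarousal_rate_nrem_per_min * dur / 60.0)):
                    ma_dur = rng.uniform(0.4, 2.5)
                    start = rng.uniform(t0, t0 + max(dur - ma_dur, 1e-3))
                    i0 = int(round(start * fm))
                    m = max(1, int(round(ma_dur * fm)))
                    snout[i0:i0 + m] += 0.5 + np.abs(
                        rng.standard_normal(min(m, nm - i0)))
            t0 += dur
    return PhysioSignals(ecog=ecog, emg=emg, sampling_rate=fs,
                         wheel=wheel, snout=snout,
                         motion_sampling_rate=fm,
                         spindle_truth=spindle_truth)


def generate_transition_ensemble(n_transitions: int = 100,
                                 true_onset_s: float = -1.5,
                                 frame_rate: float = 30.0,
                                 baseline_rate_per_frame: float = 2.0,
                                 surge_rate_per_frame: float = 10.0,
                                 surge_duration_s: float = 8.0,
                                 spacing_s: float = 40.0,
                                 tau_s: float = 0.25,
                                 seed: int = 0
                                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Poisson event-count trace with rate surges before known transitions.

    Emulates a whole-field ROA frequency trace around SWS-to-wake
    transitions: a Poisson baseline (events per frame, the ongoing
    sleep-state activity of a full field of view) with a steep rate surge
    ahead of each transition.  The surge start is calibrated so that the
    noiseless trace, smoothed with the causal ``t*exp(-t/tau)`` kernel and
    z-scored against the analytic baseline SD, crosses 2.5 exactly at
    ``true_onset_s`` relative to the transition — the ensemble's ground
    truth is defined by the same rule the estimator applies.

    Returns ``(trace, transition_times_s, calibrated_surge_start_s)``.
    """
    from .dynamics import causal_kernel, smooth_causal
    if n_transitions < 1:
        raise ValueError("need at least one transition")
    k = causal_kernel(tau_s, 1.0 / frame_rate)
    sigma_b = math.sqrt(baseline_rate_per_frame * float((k ** 2).sum()))
    # noiseless smoothed step response; solve for the surge start so the
    # 2.5 sigma crossing lands on true_onset_s
    pad = int(10 * frame_rate)
    m = int(round(surge_duration_s * frame_rate))
    step = np.concatenate([np.zeros(pad),
                           np.full(m, float(surge_rate_per_frame))])
    resp = smooth_causal(step, frame_rate, tau_s)[pad:]
    cross = int(np.argmax(resp > 2.5 * sigma_b))
    if resp[cross] <= 2.5 * sigma_b:
        raise ValueError("surge too small to cross the onset threshold")
    surge_start_s = true_onset_s - cross / frame_rate

    rng = np.random.default_rng(seed)
    total_s = spacing_s * (n_transitions + 1)
    n = int(total_s * frame_rate)
    rate = np.full(n, float(baseline_rate_per_frame))
    trans = spacing_s * (np.arange(n_transitions) + 1.0)
    for t in trans:
        i0 = int(round((t + surge_start_s) * frame_rate))
        rate[i0:i0 + m] += surge_rate_per_frame
    trace = rng.poisson(rate).astype(float)
    return trace, trans, surge_start_s


def generate_session(config: SimulationConfig) -> SyntheticSession:
    """Movie + physiology + ground-truth hypnogram from one config/seed."""
    movie, events, vessels = generate_movie(config)
    physio = generate_physiology(
        config.state_schedule,
        spindle_rate_is_per_min=config.spindle_rate_is_per_min,
        seed=config.seed + 1,
        sampling_rate=config.physio_sampling_rate,
        motion_sampling_rate=config.motion_sampling_rate)
    return SyntheticSession(movie=movie, truth_events=events,
                            hypnogram_truth=config.hypnogram(),
                            physio=physio, vessel_mask=vessels,
                            config=config)
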