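"""End-to-end pipeline: simulate/load -> detect -> score -> summarise.

``run_pipeline`` ties the modules into one reproducible run: ROA detection
on the movie, sleep-wake scoring from physiology, spindles, transitions,
transition-aligned Ca2+ traces and (when at least eight scored episodes
exist) the state-specificity PERMANOVA.  All outputs are CSVs with seed and
version headers; a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, io, metrics, overlap, physio, roa, synth
from .core import SLEEP_STATES, STATES, Hypnogram, MovieStack

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str | Path = "roawake_out"
    seed: int = 0
    movie_path: str | Path | None = None   # None -> simulate
    mask_path: str | Path | None = None
    physio_path: str | Path | None = None
    sim: synth.SimulationConfig | None = None
    roa_params: roa.RoaParams = field(default_factory=roa.RoaParams)
    scoring: physio.ScoringParams = field(
        default_factory=physio.ScoringParams)
    n_permutations: int = 999
    smooth_tau_s: float = 0.25


@dataclass
class ResultBundle:
    out_dir: Path
    events: pd.DataFrame
    hypnogram: Hypnogram
    spindles: pd.DataFrame
    transitions: pd.DataFrame
    summary: pd.DataFrame
    permanova: pd.DataFrame | None = None


def _episode_frames(ep, frame_rate: float, n_frames: int
                    ) -> tuple[int, int]:
    return (int(round(ep.start_s * frame_rate)),
            min(int(round(ep.end_s * frame_rate)), n_frames))


def summarize(events: pd.DataFrame, mask: roa.ActivityMask,
              hyp: Hypnogram, movie: MovieStack,
              spindles: list[physio.SpindleEvent],
              microarousals: list[physio.MicroarousalEvent],
              sampled_area_um2: float) -> pd.DataFrame:
    """Per-state summary: ROA frequency, active-voxel %, event morphology,
    episode counts/durations, microarousals/h and spindles/min (IS)."""
    rows = []
    hours_total = hyp.duration_s / 3600.0
    for state in STATES:
        eps = hyp.episodes_of(state)
        if not eps:
            continue
        minutes = sum(ep.duration_s for ep in eps) / 60.0
        n_ev, areas, durs, vols, frac = 0, [], [], [], []
        for ep in eps:
            f0, f1 = _episode_frames(ep, movie.frame_rate, movie.n_frames)
            if f1 <= f0:
                continue
            sel = events[(events.start_frame >= f0)
                         & (events.start_frame < f1)]
            n_ev += len(sel)
            areas.extend(sel.footprint_area_um2)
            durs.extend(sel.duration_s)
            vols.extend(sel.volume_um2s)
            frac.append(metrics.active_voxel_fraction(mask, (f0, f1)))
        freq = n_ev / (sampled_area_um2 / 100.0) / minutes if minutes else \
            float("nan")
        ma_h = float("nan")
        if state == "NREM":
            ma_h = len(microarousals) / (minutes / 60.0) if minutes else \
                float("nan")
        sp_min = physio.spindle_rate(spindles, hyp, "IS") \
            if state == "IS" else float("nan")
        rows.append({
            "state": state, "n_episodes": len(eps),
            "minutes": minutes,
            "bouts_per_h": len(eps) / hours_total,
            "mean_bout_s": 60.0 * minutes / len(eps),
            "roa_freq_per_100um2_min": freq,
            "active_voxel_pct": float(np.mean(frac)) if frac else
            float("nan"),
            "mean_area_um2": float(np.mean(areas)) if areas else
            float("nan"),
            "mean_duration_s": float(np.mean(durs)) if durs else
            float("nan"),
            "mean_volume_um2s": float(np.mean(vols)) if vols else
            float("nan"),
            "microarousals_per_h": ma_h,
            "spindles_per_min": sp_min,
        })
    return pd.DataFrame(rows)


def sleep_wake_frequency_reduction(summary: pd.DataFrame) -> float:
    """Percent reduction of mean ROA frequency in sleep vs wakefulness."""
    by_state = summary.set_index("state")
    def _mean(states):
        rows = by_state.loc[[s for s in states if s in by_state.index]]
        w = rows.minutes.to_numpy()
        f = rows.roa_freq_per_100um2_min.to_numpy()
        return float((w * f).sum() / w.sum())
    wake = _mean(("locomotion", "whisking", "quiet"))
    sleep = _mean(SLEEP_STATES)
    return 100.0 * (1.0 - sleep / wake)


def run_pipeline(config: RunConfig) -> ResultBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    t_start = time.perf_counter()

    if config.movie_path is not None:
        movie = io.read_movie(config.movie_path)
        vessels = io.read_mask(config.mask_path) \
            if config.mask_path else None
        traces, rates = io.read_physiology(config.physio_path) \
            if config.physio_path else ({}, {})
        phys = None
        if traces:
            phys = synth.PhysioSignals(
                ecog=traces["ecog"], emg=traces["emg"],
                sampling_rate=rates["ecog"], wheel=traces["wheel"],
                snout=traces["snout"], motion_sampling_rate=rates["wheel"],
                spindle_truth=[])
        truth_hyp = None
    else:
        sim = config.sim or synth.SimulationConfig(seed=seed)
        session = synth.generate_session(sim)
        movie, vessels = session.movie, session.vessel_mask
        phys = session.physio
        truth_hyp = session.hypnogram_truth
        io.write_csv(out / "truth_events.csv",
                     synth.truth_to_frame(session.truth_events), seed=seed)
        io.write_hypnogram(out / "truth_hypnogram.csv", truth_hyp,
                           seed=seed)

    result = roa.detect(movie, config.roa_params, ignore_mask=vessels)
    events = roa.events_to_frame(result.events, movie.frame_rate)
    io.write_csv(out / "events.csv", events, seed=seed,
                 extra={"k": config.roa_params.k})
    sampled_area = movie.field_area_um2 if vessels is None else \
        float((~vessels).sum()) * movie.pixel_area_um2
    log.info("detect: %d events (%.1f s)", len(events),
             time.perf_counter() - t_start)

    if phys is not None:
        rec = physio.PhysioRecording(phys.ecog, phys.emg,
                                     phys.sampling_rate)
        hyp = physio.score_session(rec, phys.wheel, phys.snout,
                                   phys.motion_sampling_rate,
                                   config.scoring)
        norm_ecog = physio.normalize_ecog(phys.ecog, phys.sampling_rate,
                                          hyp) \
            if hyp.episodes_of("NREM", True) else phys.ecog
        is_eps = [(e.start_s, e.end_s)
                  for e in hyp.episodes_of("IS", include_excluded=True)]
        spindles = physio.detect_spindles(norm_ecog, phys.sampling_rate,
                                          episodes=is_eps or None)
        transitions = physio.detect_transitions(
            hyp, phys.ecog, phys.sampling_rate)
        microarousals = physio.detect_microarousals(
            phys.snout, phys.motion_sampling_rate, hyp)
    else:
        hyp = truth_hyp or Hypnogram([])
        spindles, transitions, microarousals = [], [], []

    io.write_hypnogram(out / "hypnogram.csv", hyp, seed=seed)
    sp_df = pd.DataFrame(
        [(s.start_s, s.end_s, s.peak_time_s, s.peak_amplitude)
         for s in spindles],
        columns=["start_s", "end_s", "peak_time_s", "peak_amplitude"])
    io.write_csv(out / "spindles.csv", sp_df, seed=seed)
    tr_df = pd.DataFrame(
        [(t.from_state, t.to_state, t.time_s, t.awakening, t.refined)
         for t in transitions],
        columns=["from_state", "to_state", "time_s", "awakening",
                 "refined"])
    io.write_csv(out / "transitions.csv", tr_df, seed=seed)
    ma_df = pd.DataFrame(
        [(m.start_s, m.duration_s, m.host_episode) for m in microarousals],
        columns=["start_s", "duration_s", "host_episode"])
    io.write_csv(out / "microarousals.csv", ma_df, seed=seed)

    # transition-aligned Ca2+ traces
    freq = metrics.roa_frequency_trace(result.events, movie.n_frames,
                                       sampled_area, movie.frame_rate)
    smoothed = dynamics.smooth_causal(freq.values, movie.frame_rate,
                                      config.smooth_tau_s)
    awakenings = [t.time_s for t in transitions if t.awakening]
    aligned = dynamics.align_and_zscore(smoothed, movie.frame_rate,
                                        np.asarray(awakenings))
    al_df = pd.DataFrame(aligned.z, columns=[f"{t:.3f}"
                                             for t in aligned.times_s])
    onsets = dynamics.estimate_onset(aligned)
    al_df.insert(0, "onset_s", [o.onset_s for o in onsets])
    al_df.insert(1, "peak_z", dynamics.estimate_peak(aligned)
                 if aligned.n_transitions else [])
    io.write_csv(out / "aligned.csv", al_df, seed=seed)

    # state-specificity PERMANOVA over scored episodes
    perm_df = None
    usable = [ep for ep in hyp.episodes if not ep.excluded]
    if len(usable) >= overlap.MIN_EPISODES and \
            len({ep.state for ep in usable}) >= 2:
        heat, states = [], []
        for i, ep in enumerate(usable):
            f0, f1 = _episode_frames(ep, movie.frame_rate, movie.n_frames)
            if f1 <= f0:
                continue
            hm = metrics.compute_heatmap(result.mask, (f0, f1), ep.state, i)
            heat.append(hm.values.ravel())
            states.append(ep.state)
        states_arr = np.asarray(states)
        lv, ct = np.unique(states_arr, return_counts=True)
        keep = np.isin(states_arr, lv[ct >= 2])
        if keep.sum() >= overlap.MIN_EPISODES and \
                np.unique(states_arr[keep]).size >= 2:
            hs = overlap.EpisodeHeatmapSet(np.asarray(heat)[keep],
                                           states_arr[keep])
            res = overlap.analyze_fov(hs, config.n_permutations, seed=seed)
            perm_df = pd.DataFrame([{
                "n_episodes": int(keep.sum()), "R2": res.R2,
                "p_value": res.p_value, "pseudo_F": res.pseudo_F,
                "n_perm": res.n_permutations, "seed": res.seed}])
            io.write_csv(out / "permanova.csv", perm_df, seed=seed)

    summary = summarize(events, result.mask, hyp, movie, spindles,
                        microarousals, sampled_area)
    io.write_csv(out / "summary.csv", summary, seed=seed)
    log.info("pipeline done in %.1f s", time.perf_counter() - t_start)
    return ResultBundle(out_dir=out, events=events, hypnogram=hyp,
                        spindles=sp_df, transitions=tr_df,
                        summary=summary, permanova=perm_df)
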