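"""Region-of-activity (ROA) detection.

An ROA is a connected set of above-threshold voxels in x-y-t, treated as one
Ca2+ event.  The chain, applied to a motion-corrected movie:

A. Spatial Gaussian smoothing (sigma = 2 px) -> ``F``.
B. Temporal moving average (width 1.0 s) -> ``F_LP``; per-pixel histogram mode
   of ``F_LP`` -> baseline image ``F0``; ``S = (F - F0) / F0``.
C. Moving average of ``S`` (same 1.0 s width) -> ``S_LP``; the removed
   high-frequency residual ``S_HP = S - S_LP`` estimates the noise, and the
   per-pixel noise SD of ``S_LP`` is ``sigma = SD_t(S_HP) / sqrt(L_filt)``
   (averaging L_filt frames shrinks white noise by sqrt(L_filt)).  Slow
   fluorescence drift is removed by subtracting a 10 s moving average,
   giving ``S_BP``.  Voxels with ``S_BP > k * sigma`` (k = 5) are active.

Adjacent active voxels in space and time are grouped into single events by
3-D connected-component labelling; vessel/artifact pixels are masked out
before the grouping.  Per event the start time, spatial footprint (um^2),
volume (um^2*s) and duration (s) are recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._filters import (edge_margin, histogram_mode, moving_average,
                       window_frames)
from .core import MovieStack

log = logging.getLogger(__name__)


@dataclass
class RoaParams:
    """Tunable parameters of the detection chain (defaults as in the method).

    ``connectivity`` is 26 (faces, edges and corners of the x-y-t voxel
    neighbourhood) or 6 (faces only).
    """

    smooth_sigma_px: float = 2.0
    baseline_window_s: float = 1.0
    drift_window_s: float = 10.0
    k: float = 5.0
    connectivity: int = 26
    mode_bins: int = 100
    #: a suprathreshold voxel is kept only if the same pixel is active in
    #: an adjacent frame: genuine Ca2+ events span at least two frames
    #: (~0.07 s at 30 Hz) whereas isolated single-frame voxels are
    #: indistinguishable from threshold noise.  Set to 1 to disable.
    min_persistence_frames: int = 2
    #: "footprint" (union of active pixels over the event) or "max_instant"
    #: (largest single-frame area) for the maximal-spatial-extent descriptor.
    extent_mode: str = "footprint"

    def __post_init__(self) -> None:
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")
        if self.baseline_window_s <= 0:
            raise ValueError("baseline_window_s must be > 0")
        if self.drift_window_s <= self.baseline_window_s:
            raise ValueError("drift_window_s must exceed baseline_window_s")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.min_persistence_frames not in (1, 2):
            raise ValueError("min_persistence_frames must be 1 or 2")
        if self.extent_mode not in ("footprint", "max_instant"):
            raise ValueError("extent_mode must be 'footprint' or "
                             "'max_instant'")


@dataclass
class NoiseMap:
    """Per-pixel noise SD of the lowpass dFF series (dF/F0 units)."""

    sigma: np.ndarray
    n_degenerate: int = 0


@dataclass
class ActivityMask:
    """Boolean x-y-t activity volume plus the 2-D ignore raster.

    ``edge_margin_frames`` records how many frames at the start/end were
    excluded from thresholding because the temporal filters lacked full
    window support there (their noise is not calibrated by the sigma map).
    """

    active: np.ndarray
    ignore_mask: np.ndarray | None = None
    edge_margin_frames: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.ignore_mask is not None:
            self.ignore_mask = np.asarray(self.ignore_mask, dtype=bool)
            if self.active[:, self.ignore_mask].any():
                raise ValueError("active voxels inside the ignore mask")


@dataclass
class RoaEvent:
    """One detected spatiotemporal Ca2+ event."""

    event_id: int
    start_frame: int
    duration_s: float
    footprint_area_um2: float
    volume_um2s: float
    n_voxels: int
    bbox: tuple[int, int, int, int, int, int]  # (t0, t1, y0, y1, x0, x1) incl.
    centroid_xy: tuple[float, float] = (np.nan, np.nan)


EVENT_COLUMNS = ["event_id", "start_frame", "start_time_s", "duration_s",
                 "footprint_area_um2", "volume_um2s", "n_voxels",
                 "centroid_x", "centroid_y",
                 "bbox_t0", "bbox_t1", "bbox_y0", "bbox_y1",
                 "bbox_x0", "bbox_x1"]


def events_to_frame(events: list[RoaEvent], frame_rate: float) -> pd.DataFrame:
    rows = [(e.event_id, e.start_frame, e.start_frame / frame_rate,
             e.duration_s, e.footprint_area_um2, e.volume_um2s, e.n_voxels,
             e.centroid_xy[0], e.centroid_xy[1], *e.bbox)
            for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------- steps A-C

def spatial_smooth(movie: MovieStack, smooth_sigma_px: float = 2.0
                   ) -> MovieStack:
    """Per-frame 2-D Gaussian smoothing (step A); sigma 0 is the identity."""
    if smooth_sigma_px < 0:
        raise ValueError("smooth_sigma_px must be >= 0")
    if smooth_sigma_px == 0:
        return MovieStack(movie.data.copy(), movie.pixel_size,
                          movie.frame_rate)
    sm = ndimage.gaussian_filter(movie.data,
                                 sigma=(0, smooth_sigma_px, smooth_sigma_px))
    return MovieStack(sm, movie.pixel_size, movie.frame_rate)


def compute_baseline(movie: MovieStack, baseline_window_s: float = 1.0,
                     mode_bins: int = 100
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline image ``F0`` (step B): per-pixel mode of the lowpass series.

    Returns ``(F0, F_LP)`` where ``F_LP`` is the temporal moving average of
    the movie (width ``round(window * frame_rate)`` frames) and ``F0[p]`` the
    histogram mode of ``F_LP[:, p]``.
    """
    L = window_frames(baseline_window_s, movie.frame_rate)
    if L >= movie.n_frames:
        raise ValueError("baseline window must be shorter than the recording")
    f_lp = moving_average(movie.data, L, axis=0)
    T = f_lp.shape[0]
    f0 = histogram_mode(f_lp.reshape(T, -1).T, n_bins=mode_bins)
    return f0.reshape(movie.shape[1:]), f_lp


def compute_dff(movie: MovieStack, f0: np.ndarray,
                floor_percentile: float = 1.0) -> np.ndarray:
    """dF/F0 series ``S = (F - F0) / F0`` (step B).

    Non-positive baseline pixels are floored at the ``floor_percentile`` of
    the positive baseline values (the count is logged) so the division never
    blows up.
    """
    f0 = np.asarray(f0, dtype=np.float64)
    positive = f0[f0 > 0]
    if positive.size == 0:
        raise ValueError("baseline image has no positive pixels")
    floor = np.percentile(positive, floor_percentile)
    bad = f0 < floor
    n_floored = int(bad.sum())
    if n_floored:
        log.info("floored %d baseline pixels below %.4g", n_floored, floor)
        f0 = np.where(bad, floor, f0)
    return ((movie.data - f0[None]) / f0[None]).astype(np.float32)


def estimate_noise(s: np.ndarray, frame_rate: float,
                   baseline_window_s: float = 1.0
                   ) -> tuple[NoiseMap, np.ndarray]:
    """Noise map (step C) and the lowpass series ``S_LP``.

    ``S_LP`` is the moving average of ``S``; the residual ``S_HP = S - S_LP``
    approximates the noise of ``S``, and the noise SD of ``S_LP`` is
    ``SD_t(S_HP) / sqrt(L_filt)``.
    """
    L = window_frames(baseline_window_s, frame_rate)
    s_lp = moving_average(s, L, axis=0)
    s_hp = s - s_lp
    sigma = s_hp.std(axis=0, ddof=0) / np.sqrt(L)
    n_deg = int((sigma == 0).sum())
    if n_deg:
        log.info("%d constant pixels yield sigma 0", n_deg)
    return NoiseMap(sigma.astype(np.float64), n_deg), s_lp


def detrend(s_lp: np.ndarray, frame_rate: float,
            drift_window_s: float = 10.0) -> np.ndarray:
    """Remove slow drift: ``S_BP = S_LP - movmean(S_LP, drift_window)``."""
    L = window_frames(drift_window_s, frame_rate)
    return s_lp - moving_average(s_lp, L, axis=0)


def threshold_activity(s_bp: np.ndarray, noise: NoiseMap, k: float = 5.0,
                       ignore_mask: np.ndarray | None = None,
                       edge_margin: tuple[int, int] = (0, 0),
                       sigma_floor: float = 1e-5) -> ActivityMask:
    """Active voxels: ``S_BP > k * sigma`` outside the ignore mask (strict).

    ``edge_margin`` frames at the start/end are forced inactive: there the
    moving averages ran on a shrunken window, so their noise exceeds the
    sigma map's calibration and the threshold would be too permissive.
    Pixels whose sigma falls below ``sigma_floor`` (dF/F0 units) are
    treated as degenerate and excluded — such values are below single-
    precision resolution of the processing chain, not measured noise.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    sigma = noise.sigma
    if sigma.shape != s_bp.shape[1:]:
        raise ValueError("noise map shape does not match movie frames")
    # degenerate (zero-noise) pixels cannot be assessed: a near-zero
    # threshold would fire on numerical ripple, so they are excluded
    active = s_bp > (k * sigma)[None]
    active &= (sigma > sigma_floor)[None]
    if ignore_mask is not None:
        active &= ~np.asarray(ignore_mask, dtype=bool)[None]
    m0, m1 = edge_margin
    if m0 > 0:
        active[:m0] = False
    if m1 > 0:
        active[-m1:] = False
    return ActivityMask(active, ignore_mask, (m0, m1))


def apply_temporal_persistence(mask: ActivityMask) -> None:
    """Drop voxels whose pixel is not active in an adjacent frame.

    In-place.  Events spanning two or more frames per pixel are untouched;
    isolated single-frame voxels — the signature of threshold noise — are
    removed before component grouping.
    """
    a = mask.active
    keep = np.zeros_like(a)
    keep[1:] |= a[:-1]
    keep[:-1] |= a[1:]
    a &= keep


# ------------------------------------------------------------ event grouping

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    return ndimage.generate_binary_structure(3, 1)


def extract_roas(mask: ActivityMask, pixel_size: float, frame_rate: float,
                 connectivity: int = 26, extent_mode: str = "footprint"
                 ) -> list[RoaEvent]:
    """Group adjacent active voxels into events and compute descriptors.

    Events partition the active voxels.  ``footprint_area_um2`` is by default
    the union of the event's active pixels over its lifetime; with
    ``extent_mode='max_instant'`` it is the largest single-frame area.
    """
    labels, n = ndimage.label(mask.active, structure=_structure(connectivity))
    if n == 0:
        return []
    t_idx, y_idx, x_idx = np.nonzero(labels)
    lab = labels[t_idx, y_idx, x_idx]
    order = np.argsort(lab, kind="stable")
    lab, t_idx = lab[order], t_idx[order]
    y_idx, x_idx = y_idx[order], x_idx[order]
    bounds = np.searchsorted(lab, np.arange(1, n + 2))
    starts, ends = bounds[:-1], bounds[1:]
    px_area = pixel_size ** 2
    dt = 1.0 / frame_rate
    H = mask.active.shape[1]
    W = mask.active.shape[2]
    events: list[RoaEvent] = []
    for i in range(n):
        sl = slice(starts[i], ends[i])
        t, y, x = t_idx[sl], y_idx[sl], x_idx[sl]
        t0, t1 = int(t.min()), int(t.max())
        xy = y.astype(np.int64) * W + x
        if extent_mode == "footprint":
            n_px = np.unique(xy).size
        else:
            # largest instantaneous area across the event's frames
            n_px = int(np.bincount(t - t0).max())
        events.append(RoaEvent(
            event_id=i + 1,
            start_frame=t0,
            duration_s=(t1 - t0 + 1) * dt,
            footprint_area_um2=n_px * px_area,
            volume_um2s=t.size * px_area * dt,
            n_voxels=int(t.size),
            bbox=(t0, t1, int(y.min()), int(y.max()),
                  int(x.min()), int(x.max())),
            centroid_xy=(float(x.mean()), float(y.mean())),
        ))
    return events


# ------------------------------------------------------------------ pipeline

@dataclass
class RoaResult:
    events: list[RoaEvent]
    mask: ActivityMask
    noise: NoiseMap
    f0: np.ndarray = field(default=None, repr=False)
    s_bp: np.ndarray = field(default=None, repr=False)


def detect(movie: MovieStack, params: RoaParams | None = None,
           ignore_mask: np.ndarray | None = None,
           keep_intermediates: bool = False) -> RoaResult:
    """Full chain: movie -> event table (+ activity mask and noise map)."""
    params = params or RoaParams()
    smoothed = spatial_smooth(movie, params.smooth_sigma_px)
    f0, _ = compute_baseline(smoothed, params.baseline_window_s,
                             params.mode_bins)
    s = compute_dff(smoothed, f0)
    noise, s_lp = estimate_noise(s, movie.frame_rate,
                                 params.baseline_window_s)
    del s
    s_bp = detrend(s_lp, movie.frame_rate, params.drift_window_s)
    del s_lp
    margin = edge_margin(window_frames(params.drift_window_s,
                                       movie.frame_rate))
    mask = threshold_activity(s_bp, noise, params.k, ignore_mask,
                              edge_margin=margin)
    if params.min_persistence_frames > 1:
        apply_temporal_persistence(mask)
    events = extract_roas(mask, movie.pixel_size, movie.frame_rate,
                          params.connectivity, params.extent_mode)
    log.info("detected %d events, %d active voxels", len(events),
             int(mask.active.sum()))
    return RoaResult(events, mask, noise,
                     f0=f0 if keep_intermediates else None,
                     s_bp=s_bp if keep_intermediates else None)
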