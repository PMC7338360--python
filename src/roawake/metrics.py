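"""Summary measures derived from event tables and activity masks.

ROA frequency is expressed as events per 100 um^2 of sampled area per minute,
counting each event once at its starting frame.  Activity heatmaps give the
per-pixel fraction of active frames within an episode; hotspot overlap
compares the top-5% most-active pixels of two heatmaps by intersection over
union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .roa import ActivityMask, RoaEvent


@dataclass
class FrequencyTrace:
    """Per-frame ROA frequency (events / 100 um^2 / min)."""

    values: np.ndarray
    frame_rate: float
    sampled_area_um2: float

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


@dataclass
class ActivityHeatmap:
    """Per-pixel fraction of active frames over one episode (values in [0,1]).

    ``ignore_mask`` marks pixels excluded from the sampled area.
    """

    values: np.ndarray
    state: str = ""
    episode_id: int = -1
    ignore_mask: np.ndarray | None = None


def roa_frequency_trace(events: list[RoaEvent], n_frames: int,
                        sampled_area_um2: float, frame_rate: float
                        ) -> FrequencyTrace:
    """Events starting in each frame, normalised by area and frame duration.

    ``sampled_area_um2`` is the field area minus ignored (vessel) area.  The
    trace integrates back to the total event count:
    ``sum(values) * (area/100) * (1/(rate*60)) == len(events)``.
    """
    if sampled_area_um2 <= 0:
        raise ValueError("sampled_area_um2 must be > 0")
    starts = np.array([e.start_frame for e in events], dtype=np.intp)
    counts = np.bincount(starts, minlength=n_frames) if starts.size else \
        np.zeros(n_frames)
    per_frame_min = 1.0 / (frame_rate * 60.0)
    values = counts / (sampled_area_um2 / 100.0) / per_frame_min
    return FrequencyTrace(values.astype(np.float64), frame_rate,
                          sampled_area_um2)


def _episode_slice(frames: tuple[int, int]) -> slice:
    lo, hi = frames
    if hi <= lo:
        raise ValueError("empty episode frame range")
    return slice(lo, hi)


def active_voxel_fraction(mask: ActivityMask,
                          episode_frames: tuple[int, int] | None = None
                          ) -> float:
    """Percent of non-ignored voxels active within the episode window."""
    sl = _episode_slice(episode_frames or (0, mask.active.shape[0]))
    sub = mask.active[sl]
    if mask.ignore_mask is not None:
        keep = ~mask.ignore_mask
        n_total = sub.shape[0] * int(keep.sum())
        n_active = int(sub[:, keep].sum())
    else:
        n_total = sub.size
        n_active = int(sub.sum())
    if n_total == 0:
        raise ValueError("episode has no non-ignored voxels")
    return 100.0 * n_active / n_total


def compute_heatmap(mask: ActivityMask,
                    episode_frames: tuple[int, int] | None = None,
                    state: str = "", episode_id: int = -1) -> ActivityHeatmap:
    """Per-pixel mean of the boolean activity series over the episode."""
    sl = _episode_slice(episode_frames or (0, mask.active.shape[0]))
    values = mask.active[sl].mean(axis=0)
    return ActivityHeatmap(values.astype(np.float64), state, episode_id,
                           mask.ignore_mask)


def hotspot_pixels(heatmap: ActivityHeatmap,
                   top_fraction: float = 0.05) -> np.ndarray:
    """Binary raster of the ``top_fraction`` most-active (non-ignored) pixels.

    The cutoff is the ``1 - top_fraction`` quantile of the heatmap's
    non-ignored values; ties at the cutoff are all included, which keeps the
    selection deterministic.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    vals = heatmap.values
    keep = np.ones(vals.shape, dtype=bool) if heatmap.ignore_mask is None \
        else ~heatmap.ignore_mask
    cutoff = np.quantile(vals[keep], 1.0 - top_fraction)
    return (vals >= cutoff) & keep & (vals > 0)


def hotspot_overlap(a: ActivityHeatmap, b: ActivityHeatmap,
                    top_fraction: float = 0.05) -> float:
    """Intersection-over-union of the two heatmaps' top-5% pixel sets."""
    if a.values.shape != b.values.shape:
        raise ValueError("heatmaps must share a shape")
    if not a.values.any() or not b.values.any():
        warnings.warn("hotspot overlap undefined for an all-zero heatmap",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    sa = hotspot_pixels(a, top_fraction)
    sb = hotspot_pixels(b, top_fraction)
    union = (sa | sb).sum()
    if union == 0:
        return float("nan")
    return float((sa & sb).sum() / union)
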