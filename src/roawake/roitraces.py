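"""Conventional hand-drawn ROI trace analysis.

Mean fluorescence is averaged inside circular or polygonal ROIs; the baseline
``F0`` is the histogram mode of the trace and ``dF/F0 = (F - F0)/F0``.
Neuronal somata are neuropil-corrected by subtracting the trace of a 5 um
annulus ("doughnut") around the soma before dividing by ``F0``.  Events are
detected on the smoothed, drift-corrected ``dF/F0``: threshold 2.5x the noise
SD for the astrocytic indicator (GCaMP6f, 0.25 s smoothing) and 2x for the
neuronal one (jRGECO1a, 0.1 s smoothing); an event lasts between the
zero-crossings surrounding the threshold excursion and its amplitude is the
peak within.  Astrocytic neuropil sampling circles default to 5 um radius,
placed at least 5 um away from soma perimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk, polygon

from ._filters import histogram_mode
from .core import MovieStack

ROI_KINDS = ("astro_soma", "astro_neuropil", "neuron_soma",
             "neuron_doughnut")

#: Per-sensor smoothing sigma (s) and noise-SD threshold multiple.
SENSOR_SETTINGS = {"astro": {"smooth_sigma_s": 0.25, "threshold_sd": 2.5},
                   "neuron": {"smooth_sigma_s": 0.1, "threshold_sd": 2.0}}

NEUROPIL_RADIUS_UM = 5.0
DOUGHNUT_WIDTH_UM = 5.0


@dataclass
class RoiDefinition:
    """A circle (center px, radius px) or polygon (vertices px) ROI."""

    roi_id: str
    kind: str
    channel: str  # "astro" or "neuron"
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.channel not in ("astro", "neuron"):
            raise ValueError("channel must be 'astro' or 'neuron'")
        circle = self.center is not None and self.radius is not None
        poly = self.vertices is not None
        if circle == poly:
            raise ValueError("define either circle (center+radius) or "
                             "polygon (vertices)")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.vertices is not None:
            v = np.asarray(self.vertices, dtype=float)
            rr, cc = polygon(v[:, 1], v[:, 0], shape)
        else:
            cx, cy = self.center
            rr, cc = disk((cy, cx), self.radius, shape=shape)
        m[rr, cc] = True
        if not m.any():
            raise ValueError(f"ROI {self.roi_id!r} covers no pixels")
        return m


@dataclass
class TraceEvent:
    onset_s: float
    duration_s: float
    amplitude: float


def extract_trace(movie: MovieStack, roi: RoiDefinition) -> np.ndarray:
    """Per-frame mean fluorescence inside the ROI."""
    m = roi.mask(movie.shape[1:])
    return movie.data[:, m].mean(axis=1).astype(np.float64)


def dff_trace(f: np.ndarray, f0: float | None = None) -> np.ndarray:
    """``(F - F0)/F0`` with ``F0`` the histogram mode of the trace."""
    f = np.asarray(f, dtype=float)
    if f0 is None:
        f0 = float(histogram_mode(f))
    if f0 <= 0:
        raise ValueError("non-positive baseline mode; trace unusable")
    return (f - f0) / f0


def neuropil_correct(f_neuron: np.ndarray, f_doughnut: np.ndarray,
                     f0: float) -> np.ndarray:
    """Neuron-soma dF/F0 with neuropil subtraction:
    ``(F_neuron - F_doughnut) / F0``."""
    f_neuron = np.asarray(f_neuron, dtype=float)
    f_doughnut = np.asarray(f_doughnut, dtype=float)
    if f_neuron.shape != f_doughnut.shape:
        raise ValueError("traces must be aligned")
    if f0 <= 0:
        raise ValueError("F0 must be > 0")
    return (f_neuron - f_doughnut) / f0


def doughnut_roi(soma: RoiDefinition, pixel_size: float,
                 width_um: float = DOUGHNUT_WIDTH_UM) -> RoiDefinition:
    """A ``width_um``-wide annulus around a circular soma ROI."""
    if soma.center is None:
        raise ValueError("doughnut placement requires a circular soma ROI")
    return RoiDefinition(roi_id=f"{soma.roi_id}_doughnut",
                         kind="neuron_doughnut", channel=soma.channel,
                         center=soma.center,
                         radius=soma.radius + width_um / pixel_size)


def annulus_trace(movie: MovieStack, soma: RoiDefinition,
                  width_um: float = DOUGHNUT_WIDTH_UM) -> np.ndarray:
    """Mean trace of the annulus (doughnut minus soma)."""
    outer = doughnut_roi(soma, movie.pixel_size, width_um)
    m = outer.mask(movie.shape[1:]) & ~soma.mask(movie.shape[1:])
    if not m.any():
        raise ValueError("empty annulus")
    return movie.data[:, m].mean(axis=1).astype(np.float64)


def place_neuropil_rois(soma_rois: list[RoiDefinition],
                        shape: tuple[int, int], pixel_size: float,
                        n_rois: int, seed: int = 0,
                        radius_um: float = NEUROPIL_RADIUS_UM,
                        clearance_um: float = 5.0) -> list[RoiDefinition]:
    """Auto-place neuropil circles (5 um radius, >= 5 um from soma rims).

    Manual ROI files remain authoritative; this helper mirrors the manual
    placement rule for synthetic sessions.
    """
    rng = np.random.default_rng(seed)
    r_px = radius_um / pixel_size
    forbidden = np.zeros(shape, dtype=bool)
    for soma in soma_rois:
        grown = RoiDefinition(soma.roi_id, soma.kind, soma.channel,
                              center=soma.center,
                              radius=(soma.radius or 0)
                              + (clearance_um + radius_um) / pixel_size) \
            if soma.center is not None else soma
        forbidden |= grown.mask(shape)
    out: list[RoiDefinition] = []
    tries = 0
    while len(out) < n_rois and tries < 2000:
        tries += 1
        cy = rng.uniform(r_px, shape[0] - r_px)
        cx = rng.uniform(r_px, shape[1] - r_px)
        if forbidden[int(cy), int(cx)]:
            continue
        roi = RoiDefinition(f"neuropil_{len(out)}", "astro_neuropil",
                            "astro", center=(cx, cy), radius=r_px)
        out.append(roi)
        forbidden |= roi.mask(shape)
    return out


# ---------------------------------------------------------- event detection

def detect_trace_events(dff: np.ndarray, frame_rate: float,
                        sensor: str = "astro",
                        drift_sigma_s: float = 120.0) -> list[TraceEvent]:
    """Noise-thresholded event detection on a single dF/F0 trace.

    The trace is Gaussian-smoothed (per-sensor sigma); a heavily smoothed
    copy (sigma 120 s) is subtracted to remove drift.  The noise trace is
    the raw dF/F0 minus the smoothed trace and sets the threshold
    (``threshold_sd`` x its SD).  Events run between the zero-crossings
    around each suprathreshold excursion; the onset is the threshold
    crossing and the amplitude the in-event peak.
    """
    if sensor not in SENSOR_SETTINGS:
        raise ValueError(f"unknown sensor {sensor!r}; expected one of "
                         f"{tuple(SENSOR_SETTINGS)}")
    cfg = SENSOR_SETTINGS[sensor]
    dff = np.asarray(dff, dtype=float)
    sig = cfg["smooth_sigma_s"] * frame_rate
    if dff.size < 10 * sig:
        raise ValueError("trace too short for the smoothing width")
    smoothed = gaussian_filter1d(dff, sig)
    noise = dff - smoothed
    drift = gaussian_filter1d(dff, min(drift_sigma_s * frame_rate,
                                       dff.size / 2))
    x = smoothed - drift
    thr = cfg["threshold_sd"] * float(noise.std())
    if thr == 0:
        return []
    events: list[TraceEvent] = []
    above = x > thr
    i = 0
    n = x.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        # expand to surrounding zero-crossings
        left = i
        while left > 0 and x[left - 1] > 0:
            left -= 1
        right = i
        while right < n - 1 and x[right + 1] > 0:
            right += 1
        seg = slice(left, right + 1)
        onset_i = left + int(np.argmax(x[seg] > thr))
        events.append(TraceEvent(
            onset_s=onset_i / frame_rate,
            duration_s=(right - left + 1) / frame_rate,
            amplitude=float(x[seg].max())))
        i = right + 1
    return events


def onset_difference_histogram(astro_onsets_s: np.ndarray,
                               neuron_onsets_s: np.ndarray,
                               bin_s: float = 1.0,
                               window_s: float = 10.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of astro-minus-neuron onset differences (1 s bins).

    For every neuronal event, astrocytic onsets within ``+-window_s`` are
    collected.  Returns ``(bin_edges_s, counts)``.
    """
    edges = np.arange(-window_s, window_s + bin_s, bin_s)
    diffs = []
    astro = np.asarray(astro_onsets_s, dtype=float)
    for t in np.atleast_1d(neuron_onsets_s):
        d = astro - t
        diffs.append(d[(d >= -window_s) & (d <= window_s)])
    all_d = np.concatenate(diffs) if diffs else np.array([])
    counts, _ = np.histogram(all_d, bins=edges)
    return edges, counts
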