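"""Core containers shared across the toolbox.

Conventions
-----------
* Movies are ``(T, H, W)`` arrays: axis 0 is time (frames), axes 1-2 are image
  rows/columns. ``pixel_size`` is micrometres per pixel, ``frame_rate`` Hz.
* Times are seconds from recording start; frame indices are 0-based; intervals
  are half-open ``[start, end)``.
* The behavioural vocabulary has six states: three wake sub-states
  (``locomotion``, ``whisking``, ``quiet``) and three sleep states
  (``NREM``, ``IS``, ``REM``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAKE_STATES = ("locomotion", "whisking", "quiet")
SLEEP_STATES = ("NREM", "IS", "REM")
STATES = WAKE_STATES + SLEEP_STATES

#: Sleep episodes at or below this duration are flagged as excluded from
#: downstream state analyses (only episodes longer than 30 s are analysed).
MIN_SLEEP_EPISODE_S = 30.0


@dataclass
class MovieStack:
    """A fluorescence time series with its pixel geometry.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Fluorescence intensities (arbitrary units). Converted to float32.
    pixel_size : float
        Micrometres per pixel (square pixels assumed).
    frame_rate : float
        Acquisition rate in Hz.
    """

    data: np.ndarray
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (T, H, W), got shape "
                             f"{self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("movie contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size ** 2

    @property
    def field_area_um2(self) -> float:
        return self.data.shape[1] * self.data.shape[2] * self.pixel_area_um2


@dataclass
class Episode:
    """One behavioural episode: ``state`` over ``[start_s, end_s)``."""

    state: str
    start_s: float
    end_s: float
    excluded: bool = False

    def __post_init__(self) -> None:
        self.start_s = float(self.start_s)
        self.end_s = float(self.end_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Hypnogram:
    """Ordered, non-overlapping behavioural episodes.

    Sleep episodes of 30 s or less carry ``excluded=True``: they remain in the
    hypnogram (transitions are still defined at their boundaries) but are
    flagged out of per-state summaries.
    """

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ep in self.episodes:
            if ep.state not in STATES:
                raise ValueError(f"unknown state label {ep.state!r}; expected "
                                 f"one of {STATES}")
            if ep.end_s <= ep.start_s:
                raise ValueError("episode end must exceed start")
        for a, b in zip(self.episodes, self.episodes[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError("episodes overlap")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    @property
    def duration_s(self) -> float:
        return self.episodes[-1].end_s if self.episodes else 0.0

    def labels(self, times_s: np.ndarray) -> np.ndarray:
        """State label at each time point ('' where unscored)."""
        times_s = np.asarray(times_s, dtype=float)
        out = np.full(times_s.shape, "", dtype=object)
        for ep in self.episodes:
            out[(times_s >= ep.start_s) & (times_s < ep.end_s)] = ep.state
        return out

    def episodes_of(self, state: str, include_excluded: bool = False):
        return [ep for ep in self.episodes
                if ep.state == state and (include_excluded or not ep.excluded)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(ep.state, ep.start_s, ep.end_s, ep.excluded)
             for ep in self.episodes],
            columns=["state", "start_s", "end_s", "excluded"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hypnogram":
        eps = [Episode(str(r.state), float(r.start_s), float(r.end_s),
                       bool(r.excluded)) for r in df.itertuples()]
        return cls(eps)

    @classmethod
    def from_labels(cls, labels: np.ndarray, dt_s: float,
                    flag_short_sleep: bool = True) -> "Hypnogram":
        """Assemble episodes from a per-sample label sequence."""
        labels = np.asarray(labels, dtype=object)
        if labels.size == 0:
            return cls([])
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [labels.size]))
        eps = []
        for s, e in zip(starts, ends):
            ep = Episode(str(labels[s]), s * dt_s, e * dt_s)
            if (flag_short_sleep and ep.state in SLEEP_STATES
                    and ep.duration_s <= MIN_SLEEP_EPISODE_S):
                ep.excluded = True
            eps.append(ep)
        return cls(eps)


def per_second_accuracy(truth: Hypnogram, scored: Hypnogram,
                        dt_s: float = 1.0) -> float:
    """Fraction of time points (default 1 s grid) with matching labels."""
    t_end = min(truth.duration_s, scored.duration_s)
    times = np.arange(0.0, t_end, dt_s) + dt_s / 2.0
    if times.size == 0:
        raise ValueError("no overlap between hypnograms")
    return float(np.mean(truth.labels(times) == scored.labels(times)))
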