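"""File-format plumbing: TIFF movies with JSON sidecars, CSV tables.

Every CSV written here carries a ``#``-prefixed header recording the library
version, the seed and the time conventions (seconds from recording start,
0-based frames, half-open intervals), so outputs are self-describing and
reruns can be compared byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import Hypnogram, MovieStack

SIDECAR_KEYS = ("pixel_size_um", "frame_rate_hz")


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Multi-page TIFF plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    sidecar = {"pixel_size_um": movie.pixel_size,
               "frame_rate_hz": movie.frame_rate}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> MovieStack:
    """Load a movie written by :func:`write_movie` (value-identical)."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar_path} (required keys: "
            f"{', '.join(SIDECAR_KEYS)})")
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar_path} is missing required keys: "
                       f"{', '.join(missing)}")
    data = tifffile.imread(path)
    return MovieStack(np.asarray(data), float(meta["pixel_size_um"]),
                      float(meta["frame_rate_hz"]))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8),
                     photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)


def write_csv(path: str | Path, df: pd.DataFrame, seed: int | None = None,
              extra: dict | None = None) -> None:
    """CSV with a structured comment header."""
    lines = [f"# roawake {__version__}",
             "# time: seconds from recording start; frames 0-based; "
             "intervals half-open [start, end)"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n",
                  float_format="%.10g")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")


def write_hypnogram(path: str | Path, hyp: Hypnogram,
                    seed: int | None = None) -> None:
    write_csv(path, hyp.to_frame(), seed=seed)


def read_hypnogram(path: str | Path) -> Hypnogram:
    return Hypnogram.from_frame(read_csv(path))


def write_physiology(path: str | Path, traces: dict[str, np.ndarray],
                     sampling_rates: dict[str, float]) -> None:
    """HDF5-style container (npz is used for portability) with rate attrs."""
    payload = {k: np.asarray(v) for k, v in traces.items()}
    payload.update({f"{k}__rate_hz": np.asarray(v)
                    for k, v in sampling_rates.items()})
    np.savez(Path(path), **payload)


def read_physiology(path: str | Path
                    ) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    with np.load(Path(path)) as data:
        traces = {k: data[k] for k in data.files if "__rate_hz" not in k}
        rates = {k.replace("__rate_hz", ""): float(data[k])
                 for k in data.files if "__rate_hz" in k}
    return traces, rates
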