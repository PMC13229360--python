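"""Keypoint trajectory container and the canonical CSV dialect.

The canonical file is a flat, diff-able CSV: one ``#`` metadata line
(sample rate, coordinate frame, start time), then a header
``time_s,<name>_x,<name>_y,<name>_z,...`` with positions in meters.

Two ingest dialects are recognized. ``markerless`` streams must carry
the heel and head keypoints the pipeline consumes (left_heel,
right_heel, left_ear, right_ear, nose); ``markered`` streams carry
left_foot, right_foot and head (sacrum optional). Per the conventions
used throughout: "foot position" means the heel keypoint, x is
anterior-posterior (+ forward), y mediolateral (+ to the subject's
left), z up.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataQualityError, FormatError, MissingKeypointError
from .signals import ScalarSeries

__all__ = [
    "KeypointTrajectory",
    "REQUIRED_KEYPOINTS",
    "read_keypoints",
    "write_keypoints",
    "read_ground_truth_json",
]

REQUIRED_KEYPOINTS = {
    "markerless": ("left_heel", "right_heel", "left_ear", "right_ear", "nose"),
    "markered": ("left_foot", "right_foot", "head"),
}

#: timestamps may deviate from a uniform grid by at most this much (s)
TIME_TOLERANCE = 1e-4

#: isolated gaps up to this many samples are linearly interpolated
DEFAULT_MAX_GAP = 5


@dataclass
class KeypointTrajectory:
    """Uniformly sampled 3D positions for a set of named keypoints.

    ``positions[name]`` is an (n_samples, 3) float array in meters.
    ``frame_tag`` is ``"raw"`` for capture coordinates and ``"walkway"``
    after the walkway frame has been applied.
    """

    sample_rate: float
    positions: dict[str, np.ndarray]
    t0: float = 0.0
    frame_tag: str = "raw"

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        clean = {}
        n = None
        for name, arr in self.positions.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"positions[{name!r}] must have shape (n, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all keypoints must share one time base")
            clean[name] = arr
        self.positions = clean

    @property
    def names(self) -> list[str]:
        return list(self.positions)

    @property
    def n_samples(self) -> int:
        return next(iter(self.positions.values())).shape[0] if self.positions else 0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def get(self, name: str, context: str = "") -> np.ndarray:
        try:
            return self.positions[name]
        except KeyError:
            raise MissingKeypointError(name, context) from None

    def axis_series(self, name: str, axis: int, units: str = "m") -> ScalarSeries:
        """One coordinate of one keypoint as a ScalarSeries."""
        return ScalarSeries(
            sample_rate=self.sample_rate,
            values=self.get(name)[:, axis],
            t0=self.t0,
            units=units,
        )

    def translated(self, offset) -> "KeypointTrajectory":
        off = np.asarray(offset, dtype=float).reshape(3)
        return replace(
            self, positions={k: v + off for k, v in self.positions.items()}
        )

    def shifted(self, dt: float) -> "KeypointTrajectory":
        """Same samples with the time origin moved by ``dt`` seconds."""
        return replace(self, t0=self.t0 + dt)


def _interpolate_gaps(col: np.ndarray, name: str, times, max_gap: int) -> np.ndarray:
    bad = ~np.isfinite(col)
    if not bad.any():
        return col
    idx = np.arange(col.size)
    # locate runs of consecutive NaN samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        run = stop - start
        if run > max_gap or start == 0 or stop == col.size:
            raise DataQualityError(
                f"keypoint {name!r}: gap of {run} samples at "
                f"t={times[start]:.4f}..{times[stop - 1]:.4f} s exceeds the "
                f"{max_gap}-sample interpolation limit"
            )
    good = ~bad
    out = col.copy()
    out[bad] = np.interp(idx[bad], idx[good], col[good])
    return out


def read_keypoints(
    path,
    dialect: str = "markerless",
    sample_rate: float | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> KeypointTrajectory:
    """Read a canonical keypoint CSV.

    ``sample_rate`` overrides the file's metadata line; one of the two
    must provide it. Isolated missing samples (gaps of at most
    ``max_gap``) are linearly interpolated; longer gaps raise
    :class:`DataQualityError`.
    """
    if dialect not in REQUIRED_KEYPOINTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for item in first.lstrip("#").strip().split(","):
                if "=" in item:
                    k, v = item.split("=", 1)
                    meta[k.strip()] = v.strip()
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    if "time_s" not in df.columns:
        raise FormatError("missing 'time_s' column")
    if sample_rate is None:
        if "sample_rate_hz" not in meta:
            raise FormatError("sample rate neither in metadata nor supplied")
        sample_rate = float(meta["sample_rate_hz"])
    frame_tag = meta.get("frame", "raw")

    names = []
    for col in df.columns:
        if col.endswith("_x"):
            base = col[:-2]
            if f"{base}_y" in df.columns and f"{base}_z" in df.columns:
                names.append(base)
    for req in REQUIRED_KEYPOINTS[dialect]:
        if req not in names:
            raise MissingKeypointError(req, f"dialect {dialect!r}, file {path.name}")

    t = df["time_s"].to_numpy(dtype=float)
    t0 = float(t[0]) if t.size else float(meta.get("t0_s", 0.0))
    if t.size > 1:
        expected = t0 + np.arange(t.size) / sample_rate
        if np.max(np.abs(t - expected)) > TIME_TOLERANCE:
            raise FormatError(
                f"timestamps deviate from a uniform {sample_rate:g} Hz grid "
                f"by more than {TIME_TOLERANCE:g} s"
            )
    positions = {}
    for name in names:
        cols = np.column_stack(
            [df[f"{name}_{ax}"].to_numpy(dtype=float) for ax in "xyz"]
        )
        for j in range(3):
            cols[:, j] = _interpolate_gaps(cols[:, j], name, t, max_gap)
        positions[name] = cols
    return KeypointTrajectory(
        sample_rate=float(sample_rate), positions=positions, t0=t0, frame_tag=frame_tag
    )


def write_keypoints(traj: KeypointTrajectory, path) -> None:
    """Write the canonical CSV; round-trips through :func:`read_keypoints`."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": traj.times}
    for name in traj.names:
        arr = traj.positions[name]
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(
            f"# sample_rate_hz={traj.sample_rate!r}, frame={traj.frame_tag}, "
            f"t0_s={traj.t0!r}\n"
        )
        df.to_csv(fh, index=False, float_format="%.9f")


def read_ground_truth_json(path) -> dict:
    """Load a simulator ground-truth sidecar (see synth module schema)."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
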