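"""Walkway coordinate frame from three calibration stances.

The capture volume is oriented by having the subject stand at three
known spots: the walkway start, a point a known distance forward along
the walkway (default 5 m), and a point a known distance to the right
(default 1 m). These define origin and axes (x forward, y to the
subject's left, z up) and, because the distances are known, a per-axis
multiplicative correction for calibration bias in absolute scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DataQualityError, DegenerateFrameError
from .io import KeypointTrajectory

__all__ = ["WalkwayFrame", "fit_walkway_frame", "apply_frame", "unapply_frame"]

#: plausible band for the per-axis bias correction; scale estimates far
#: outside it indicate a failed calibration rather than ordinary bias
SCALE_BAND = (0.8, 1.2)


@dataclass(frozen=True)
class WalkwayFrame:
    """Rigid transform plus per-axis scale: p_walkway = S·R·(p_raw − origin)."""

    origin: np.ndarray
    rotation: np.ndarray  # 3x3, rows are the walkway axes in raw coords
    axis_scale: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, float).reshape(3, 3)
        )
        object.__setattr__(
            self, "axis_scale", np.asarray(self.axis_scale, float).reshape(3)
        )
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    def transform(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p - self.origin) @ self.rotation.T * self.axis_scale

    def untransform(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p / self.axis_scale) @ self.rotation + self.origin

    def to_json(self, path) -> None:
        payload = {
            "origin": self.origin.tolist(),
            "rotation": self.rotation.tolist(),
            "axis_scale": self.axis_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "WalkwayFrame":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(d["origin"], d["rotation"], d["axis_scale"])


def fit_walkway_frame(
    p_origin,
    p_forward,
    p_right,
    forward_dist: float = 5.0,
    right_dist: float = 1.0,
) -> WalkwayFrame:
    """Fit the walkway frame from the three calibration points.

    The forward axis runs from ``p_origin`` to ``p_forward``; the
    mediolateral axis is the component of ``p_origin``→``p_right``
    orthogonal to it (negated: y is positive to the subject's left, and
    the third point is to the *right*); z completes a right-handed
    frame. AP and ML scales are set so the mapped calibration distances
    equal the known ``forward_dist`` and ``right_dist`` exactly; the
    vertical scale, unobservable from floor-plane points, defaults to
    the mean of the two horizontal scales.
    """
    p_origin = np.asarray(p_origin, float).reshape(3)
    p_forward = np.asarray(p_forward, float).reshape(3)
    p_right = np.asarray(p_right, float).reshape(3)
    fwd = p_forward - p_origin
    d_fwd = np.linalg.norm(fwd)
    if d_fwd < 1e-9:
        raise DegenerateFrameError("origin and forward points coincide")
    ex = fwd / d_fwd
    rgt = p_right - p_origin
    ml = rgt - (rgt @ ex) * ex
    d_ml = np.linalg.norm(ml)
    if d_ml < 1e-9 * max(1.0, np.linalg.norm(rgt)):
        raise DegenerateFrameError("calibration points are collinear")
    ey = -ml / d_ml  # third point is to the right; +y is to the left
    ez = np.cross(ex, ey)
    scale_x = forward_dist / d_fwd
    scale_y = right_dist / d_ml
    for label, s in (("AP", scale_x), ("ML", scale_y)):
        if not (SCALE_BAND[0] <= s <= SCALE_BAND[1]):
            raise DataQualityError(
                f"{label} axis scale {s:.3f} outside plausible band {SCALE_BAND}; "
                "check calibration stance positions"
            )
    scale_z = 0.5 * (scale_x + scale_y)
    return WalkwayFrame(
        origin=p_origin,
        rotation=np.vstack([ex, ey, ez]),
        axis_scale=np.array([scale_x, scale_y, scale_z]),
    )


def apply_frame(traj: KeypointTrajectory, frame: WalkwayFrame) -> KeypointTrajectory:
    """Map a raw-frame trajectory into walkway coordinates."""
    if traj.frame_tag != "raw":
        raise ValueError(
            f"trajectory is already in frame {traj.frame_tag!r}; "
            "apply_frame expects raw capture coordinates"
        )
    positions = {k: frame.transform(v) for k, v in traj.positions.items()}
    return replace(traj, positions=positions, frame_tag="walkway")


def unapply_frame(traj: KeypointTrajectory, frame: WalkwayFrame) -> KeypointTrajectory:
    """Exact inverse of :func:`apply_frame`."""
    if traj.frame_tag != "walkway":
        raise ValueError("unapply_frame expects walkway-frame data")
    positions = {k: frame.untransform(v) for k, v in traj.positions.items()}
    return replace(traj, positions=positions, frame_tag="raw")
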