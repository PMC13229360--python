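"""Spatiotemporal step metrics, head speed, and bout summaries.

Step length and width are the anterior-posterior and mediolateral
displacements between consecutive footstep locations (signed width
positive leftward); head speed is the time derivative of the average
forward position of the head keypoints; the bout summary carries the
supplemental measures used for scoring: movement duration, mean and
maximum speed, maximum/mean step width, and the maximum lateral
footstep deviation outside the marked walkway (half-width 15.24 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingKeypointError
from .events import BoutWindow, StanceInterval
from .io import KeypointTrajectory
from .signals import ScalarSeries, derivative, lowpass

__all__ = [
    "StepRecord",
    "BoutSummary",
    "step_metrics",
    "head_speed",
    "bout_summary",
    "swing_apexes",
    "obstacle_clearance",
    "WALKWAY_HALFWIDTH",
]

#: half of the 30.48 cm marked walkway width
WALKWAY_HALFWIDTH = 0.1524

MARKERLESS_HEAD = ("left_ear", "right_ear", "nose")


@dataclass(frozen=True)
class StepRecord:
    """One step: displacement between two consecutive footsteps."""

    index: int
    leading_side: str
    step_length: float  # m, AP displacement
    step_width_signed: float  # m, ML displacement, + leftward
    step_width: float  # m, |ML displacement|
    step_period: float  # s, midstance-to-midstance
    midstance_time: float  # s, of the leading (later) footstep

    def __post_init__(self):
        if self.step_period <= 0:
            raise ValueError("step_period must be positive")


@dataclass
class BoutSummary:
    duration: float
    mean_speed: float
    max_speed: float
    distance_speed: float  # AP displacement / duration, the stopwatch analogue
    n_steps: int
    max_lateral_placement: float
    max_step_width: float | None
    mean_step_width: float | None
    head_speed: ScalarSeries | None = None
    flags: list = field(default_factory=list)


def step_metrics(footsteps: list[StanceInterval]) -> list[StepRecord]:
    """Per-step length/width/period from time-ordered footsteps."""
    ordered = sorted(footsteps, key=lambda s: s.midstance_time)
    records = []
    for i, (a, b) in enumerate(zip(ordered, ordered[1:])):
        d = b.footstep_location - a.footstep_location
        records.append(
            StepRecord(
                index=i,
                leading_side=b.side,
                step_length=float(d[0]),
                step_width_signed=float(d[1]),
                step_width=float(abs(d[1])),
                step_period=float(b.midstance_time - a.midstance_time),
                midstance_time=float(b.midstance_time),
            )
        )
    return records


def head_speed(traj: KeypointTrajectory, cutoff: float = 3.0) -> ScalarSeries:
    """Signed forward speed of the head (m/s).

    Markerless streams average the AP position of left ear, right ear
    and nose; markered streams use the single head marker. The
    derivative is low-passed at ``cutoff`` and keeps its sign, so the
    return leg of a pivot trial is negative.
    """
    if all(k in traj.positions for k in MARKERLESS_HEAD):
        ap = np.mean([traj.positions[k][:, 0] for k in MARKERLESS_HEAD], axis=0)
    elif "head" in traj.positions:
        ap = traj.positions["head"][:, 0]
    else:
        raise MissingKeypointError(
            "left_ear/right_ear/nose or head", "head_speed"
        )
    s = ScalarSeries(traj.sample_rate, ap, t0=traj.t0, units="m")
    return lowpass(derivative(s), cutoff)


def bout_summary(
    steps: list[StepRecord],
    footsteps: list[StanceInterval],
    head_spd: ScalarSeries,
    bout: BoutWindow,
    walkway_halfwidth: float = WALKWAY_HALFWIDTH,
) -> BoutSummary:
    """Aggregate a bout into the measures the FGA scorer consumes.

    ``mean_speed`` averages the signed head speed over the bout window
    (the primary speed measure); ``distance_speed`` is AP head
    displacement over duration, the stopwatch-style alternative.
    ``max_lateral_placement`` is how far any footstep strayed outside
    the walkway edge, zero when all steps stayed inside.
    """
    duration = bout.t_end - bout.t_start
    win = head_spd.slice_time(bout.t_start, bout.t_end)
    mean_speed = float(np.mean(win.values))
    max_speed = float(np.max(np.abs(win.values)))
    # integrate speed for displacement (robust to pivot sign reversals)
    disp = float(abs(np.trapezoid(win.values, dx=1.0 / win.sample_rate)))
    flags = []
    if footsteps:
        lateral = np.array([abs(s.footstep_location[1]) for s in footsteps])
        max_lat = float(np.max(np.maximum(lateral - walkway_halfwidth, 0.0)))
    else:
        max_lat = 0.0
        flags.append("no footsteps inside bout")
    if steps:
        widths = np.array([s.step_width for s in steps])
        max_w, mean_w = float(widths.max()), float(widths.mean())
    else:
        max_w = mean_w = None
        flags.append("no steps: width statistics undefined")
    return BoutSummary(
        duration=float(duration),
        mean_speed=mean_speed,
        max_speed=max_speed,
        distance_speed=disp / duration,
        n_steps=len(steps),
        max_lateral_placement=max_lat,
        max_step_width=max_w,
        mean_step_width=mean_w,
        head_speed=head_spd,
        flags=flags,
    )


def swing_apexes(traj: KeypointTrajectory,
                 stances: list[StanceInterval]) -> list[tuple[str, float, float]]:
    """Maximum heel height of each swing, attributed to the landing step.

    For every pair of consecutive same-side stances, the peak heel z
    between the first stance's end and the next stance's start. Returns
    (side, landing_midstance_time, apex_height) tuples.
    """
    out = []
    t = traj.times
    for side in ("left", "right"):
        key = f"{side}_heel" if f"{side}_heel" in traj.positions else f"{side}_foot"
        z = traj.get(key)[:, 2]
        own = sorted([s for s in stances if s.side == side],
                     key=lambda s: s.midstance_time)
        for a, b in zip(own, own[1:]):
            mask = (t > a.end) & (t < b.start)
            if mask.any():
                out.append((side, b.midstance_time, float(z[mask].max())))
    return out


def obstacle_clearance(apexes: list[tuple[str, float, float]]) -> float | None:
    """Extra heel lift of the highest swing over the typical swing.

    The obstacle-crossing step is the swing with the highest apex; its
    clearance is that apex minus the median apex of all other swings.
    Returns None with fewer than 2 swings.
    """
    if len(apexes) < 2:
        return None
    heights = np.array([h for _, _, h in apexes])
    i = int(np.argmax(heights))
    rest = np.delete(heights, i)
    return float(heights[i] - np.median(rest))
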