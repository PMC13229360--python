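"""Per-trial analysis: from a walkway-frame trajectory to events,
steps and a bout summary. This is the composition the CLI, the FGA
report builder and the two-system validation all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import (
    BoutWindow,
    EventConfig,
    StanceInterval,
    check_alternation,
    detect_bout,
    detect_stances,
    foot_speed,
    sum_foot_speed,
)
from .io import KeypointTrajectory
from .signals import ScalarSeries
from .steps import (
    WALKWAY_HALFWIDTH,
    BoutSummary,
    StepRecord,
    bout_summary,
    head_speed,
    step_metrics,
    swing_apexes,
)

__all__ = ["TrialAnalysis", "analyze_trial"]

#: stances starting within this margin of the bout edges still belong
#: to the bout (filter widening shifts threshold crossings slightly)
BOUT_EDGE_TOL = 0.25  # s


@dataclass
class TrialAnalysis:
    bout: BoutWindow
    footsteps: list[StanceInterval]
    steps: list[StepRecord]
    head_spd: ScalarSeries
    summary: BoutSummary
    apexes: list
    flags: list = field(default_factory=list)


def analyze_trial(
    traj: KeypointTrajectory,
    cfg: EventConfig = EventConfig(),
    walkway_halfwidth: float = WALKWAY_HALFWIDTH,
) -> TrialAnalysis:
    """Run the full event/metric chain on one walking trial.

    Stances whose start falls inside the detected bout (within a small
    edge tolerance) are the bout's footsteps; standing periods before
    gait initiation and after termination are excluded by construction
    since their stance regions start at the recording edges.
    """
    if traj.frame_tag != "walkway":
        raise ValueError("analyze_trial expects walkway-frame data")
    bout = detect_bout(sum_foot_speed(traj, cfg), cfg)
    stances: list[StanceInterval] = []
    for side in ("left", "right"):
        spd = foot_speed(traj, side, cfg)
        stances.extend(detect_stances(spd, traj, side, cfg))
    footsteps = sorted(
        (
            s
            for s in stances
            if bout.t_start - BOUT_EDGE_TOL <= s.start <= bout.t_end + BOUT_EDGE_TOL
        ),
        key=lambda s: s.midstance_time,
    )
    steps = step_metrics(footsteps)
    hs = head_speed(traj, cutoff=cfg.foot_speed_cutoff)
    summary = bout_summary(steps, footsteps, hs, bout, walkway_halfwidth)
    flags = check_alternation(footsteps) + summary.flags
    return TrialAnalysis(
        bout=bout,
        footsteps=footsteps,
        steps=steps,
        head_spd=hs,
        summary=summary,
        apexes=swing_apexes(traj, footsteps),
        flags=flags,
    )
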