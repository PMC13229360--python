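"""End-to-end two-system validation: align, register, detect steps in
both streams, pair them, and summarize agreement per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import (
    AlignmentResult,
    PairedSteps,
    bland_altman,
    ols_with_ci,
    pair_steps,
    spatial_register,
    time_align,
)
from .events import EventConfig, detect_bout, detect_stances, foot_speed, sum_foot_speed
from .io import KeypointTrajectory
from .signals import resample_linear
from .steps import head_speed, step_metrics
from .pipeline import BOUT_EDGE_TOL

__all__ = ["PairedTrial", "extract_paired_trial", "summarize_agreement"]


@dataclass
class PairedTrial:
    """Aligned, registered per-step and head-speed pairs of one trial."""

    alignment: AlignmentResult
    paired: PairedSteps
    length_ml: np.ndarray
    length_mk: np.ndarray
    width_ml: np.ndarray  # signed
    width_mk: np.ndarray
    head_ml: np.ndarray
    head_mk: np.ndarray


def _bout_footsteps(traj, cfg):
    bout = detect_bout(sum_foot_speed(traj, cfg), cfg)
    stances = []
    for side in ("left", "right"):
        spd = foot_speed(traj, side, cfg)
        stances.extend(detect_stances(spd, traj, side, cfg))
    inside = [
        s for s in stances
        if bout.t_start - BOUT_EDGE_TOL <= s.start <= bout.t_end + BOUT_EDGE_TOL
    ]
    return bout, sorted(inside, key=lambda s: s.midstance_time)


def extract_paired_trial(
    markerless: KeypointTrajectory,
    markered: KeypointTrajectory,
    cfg: EventConfig = EventConfig(),
    max_time_gap: float = 0.3,
) -> PairedTrial:
    """Align a simultaneous recording pair and pair up its steps.

    The markerless clock is shifted by the recovered lag and its space
    registered to the markered stream at the first sample; steps are
    then detected independently in each stream and matched by
    midstance time. Head speed is compared pointwise over the common
    bout at the markered rate.
    """
    align = time_align(sum_foot_speed(markerless, cfg),
                       sum_foot_speed(markered, cfg))
    ml = markerless.shifted(-align.lag)
    ml = spatial_register(markered, ml)
    bout_mk, foot_mk = _bout_footsteps(markered, cfg)
    _, foot_ml = _bout_footsteps(ml, cfg)
    # pair footstep events first, then derive each system's step vectors
    # between consecutively *paired* footsteps: a footstep missed by one
    # system lengthens the same step in both streams instead of pairing
    # a double step against a single one
    paired = pair_steps(foot_ml, foot_mk, max_time_gap=max_time_gap)
    steps_ml = step_metrics([a for a, _ in paired.pairs])
    steps_mk = step_metrics([b for _, b in paired.pairs])
    length_ml = np.array([s.step_length for s in steps_ml])
    length_mk = np.array([s.step_length for s in steps_mk])
    width_ml = np.array([s.step_width_signed for s in steps_ml])
    width_mk = np.array([s.step_width_signed for s in steps_mk])

    hs_ml = resample_linear(head_speed(ml, cfg.foot_speed_cutoff),
                            markered.sample_rate)
    hs_mk = head_speed(markered, cfg.foot_speed_cutoff)
    t_lo = max(hs_ml.t0, hs_mk.t0, bout_mk.t_start)
    t_hi = min(hs_ml.times[-1], hs_mk.times[-1], bout_mk.t_end)
    win_ml = hs_ml.slice_time(t_lo, t_hi)
    win_mk = hs_mk.slice_time(t_lo, t_hi)
    n = min(win_ml.n, win_mk.n)
    return PairedTrial(
        alignment=align,
        paired=paired,
        length_ml=length_ml,
        length_mk=length_mk,
        width_ml=width_ml,
        width_mk=width_mk,
        head_ml=win_ml.values[:n],
        head_mk=win_mk.values[:n],
    )


def summarize_agreement(ml_values, mk_values) -> dict:
    """Regression (markered on markerless) plus Bland-Altman
    (markerless − markered) for one pooled metric."""
    reg = ols_with_ci(np.asarray(ml_values), np.asarray(mk_values))
    ba = bland_altman(np.asarray(ml_values), np.asarray(mk_values))
    return {"regression": reg, "bland_altman": ba}
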