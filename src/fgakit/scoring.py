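"""Automated FGA scoring for Conditions 2-6.

Each scored condition compares a measured speed (and, for Conditions
3/4, lateral foot placement; for 5, turn duration; for 6, obstacle
clearance) against the Condition-1 "Gait Level Surface" baseline and
emits an integer score 0-3 with the exact rule branch that fired.

The printed threshold intervals share endpoints (e.g. Condition 2's
[110%, 125%] and [105%, 110%] bands both print 110%). The convention
here: every band is inclusive at its lower bound, the *higher* score's
band owns a shared endpoint, and when several bands apply the highest
score wins. Conditions 1 and 7-10 carry measured metrics only — no
quantitative rules exist for them — and are reported unscored.

All thresholds are configuration, not constants: clinicians may edit
them, and every report embeds the values actually used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .errors import FgaError
from .events import EventConfig
from .io import KeypointTrajectory
from .pipeline import TrialAnalysis, analyze_trial
from .signals import ScalarSeries
from .steps import MARKERLESS_HEAD, obstacle_clearance

__all__ = [
    "ScoringThresholds",
    "ConditionResult",
    "FGAReport",
    "score_condition2",
    "score_condition34",
    "score_condition5",
    "score_condition6",
    "detect_turn_duration",
    "build_report",
]

SOFTWARE_VERSION = "0.1.0"

CONDITION_NAMES = {
    1: "Gait Level Surface",
    2: "Change in Gait Speed",
    3: "Gait with Horizontal Head Turns",
    4: "Gait with Vertical Head Turns",
    5: "Gait and Pivot Turn",
    6: "Step Over Obstacle",
    7: "Gait with Narrow Base of Support",
    8: "Gait with Eyes Closed",
    9: "Ambulating Backwards",
    10: "Steps",
}


@dataclass(frozen=True)
class ScoringThresholds:
    """Editable scoring thresholds; defaults are the published rules.

    Speed bounds are ratios to the Condition-1 mean speed (1.0 = no
    change). ``clearance_high`` separates "high" from "low" obstacle
    clearance — the rules name the distinction without a number, so it
    is a documented default, not a claim. ``turn_speed_threshold`` is
    the forward-speed magnitude whose last/first crossing brackets the
    pivot turn.
    """

    cond2_score3: float = 1.25  # ratio above which speed change scores 3
    cond2_score2_low: float = 1.10
    cond2_score1_low: float = 1.05
    cond34_score3_band: tuple = (0.95, 1.05)
    cond34_score2_band: tuple = (0.90, 1.10)
    cond34_score1_low: float = 0.75
    lateral_limit: float = 0.1524  # m outside the walkway edge
    cond5_score3_max: float = 3.0  # s
    cond5_score2_max: float = 4.5  # s
    cond6_speed_floor: float = 0.75  # ratio
    clearance_high: float = 0.10  # m above the typical swing apex
    turn_speed_threshold: float = 0.2  # m/s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cond34_score3_band"] = list(self.cond34_score3_band)
        d["cond34_score2_band"] = list(self.cond34_score2_band)
        return d


@dataclass
class ConditionResult:
    condition_id: int
    score: int | None  # None = unscored (conditions 1, 7-10 or failed trial)
    ratio_to_baseline: float | None
    rule_fired: str
    completed: bool
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.score is not None and self.score not in (0, 1, 2, 3):
            raise ValueError("score must be 0-3 or None")


def _result(cond, score, ratio, rule, completed=True, metrics=None):
    return ConditionResult(
        condition_id=cond, score=score, ratio_to_baseline=ratio,
        rule_fired=rule, completed=completed, metrics=metrics or {},
    )


def score_condition2(
    mean_speed_fast: float, baseline: float,
    th: ScoringThresholds = ScoringThresholds(),
) -> ConditionResult:
    """Change in Gait Speed: ratio of fast-walk to baseline mean speed.

    3 if the ratio exceeds 125%; 2 in [110%, 125%]; 1 in [105%, 110%);
    0 with no increase beyond 105%.
    """
    if baseline <= 0:
        raise ValueError("baseline speed must be positive")
    r = mean_speed_fast / baseline
    if r > th.cond2_score3:
        score, rule = 3, f"ratio {r:.3f} > {th.cond2_score3:.2f}"
    elif r >= th.cond2_score2_low:
        score, rule = 2, (
            f"ratio {r:.3f} in [{th.cond2_score2_low:.2f}, {th.cond2_score3:.2f}]"
        )
    elif r >= th.cond2_score1_low:
        score, rule = 1, (
            f"ratio {r:.3f} in [{th.cond2_score1_low:.2f}, {th.cond2_score2_low:.2f})"
        )
    else:
        score, rule = 0, f"ratio {r:.3f} < {th.cond2_score1_low:.2f}"
    return _result(2, score, r, rule,
                   metrics={"mean_speed": mean_speed_fast, "baseline": baseline})


def score_condition34(
    max_speed: float, baseline: float, max_lateral: float,
    th: ScoringThresholds = ScoringThresholds(), condition_id: int = 3,
) -> ConditionResult:
    """Gait with head turns: maximum speed ratio plus a lateral rule.

    3 when the maximum-speed ratio stays within [95%, 105%] of the
    baseline, 2 within [90%, 110%], 1 within [75%, 90%) or outside
    the 110% band, 0 below 75%. A footstep deviating beyond
    ``lateral_limit`` outside the walkway caps the score at 1.
    """
    if baseline <= 0:
        raise ValueError("baseline speed must be positive")
    r = max_speed / baseline
    lo3, hi3 = th.cond34_score3_band
    lo2, hi2 = th.cond34_score2_band
    if r < th.cond34_score1_low:
        score, rule = 0, f"ratio {r:.3f} < {th.cond34_score1_low:.2f}"
    elif r < lo2:
        score, rule = 1, f"ratio {r:.3f} in [{th.cond34_score1_low:.2f}, {lo2:.2f})"
    elif lo3 <= r <= hi3:
        score, rule = 3, f"ratio {r:.3f} in [{lo3:.2f}, {hi3:.2f}]"
    elif lo2 <= r <= hi2:
        score, rule = 2, f"ratio {r:.3f} in [{lo2:.2f}, {hi2:.2f}]"
    else:
        score, rule = 1, f"ratio {r:.3f} > {hi2:.2f} (speed change out of band)"
    if max_lateral > th.lateral_limit and score > 1:
        score = 1
        rule += (
            f"; lateral deviation {max_lateral:.3f} m > limit "
            f"{th.lateral_limit:.4f} m caps score at 1"
        )
    return _result(condition_id, score, r, rule,
                   metrics={"max_speed": max_speed, "baseline": baseline,
                            "max_lateral": max_lateral})


def score_condition5(
    duration: float, completed: bool,
    th: ScoringThresholds = ScoringThresholds(),
) -> ConditionResult:
    """Gait and Pivot Turn: 3 under 3 s, 2 up to 4.5 s, 1 beyond,
    0 when the turn was not completed."""
    if completed and duration < 0:
        raise ValueError("turn duration cannot be negative")
    if not completed:
        return _result(5, 0, None, "turn not completed", completed=False)
    if duration < th.cond5_score3_max:
        score, rule = 3, f"turn {duration:.2f} s < {th.cond5_score3_max:g} s"
    elif duration <= th.cond5_score2_max:
        score, rule = 2, (
            f"turn {duration:.2f} s in [{th.cond5_score3_max:g}, "
            f"{th.cond5_score2_max:g}] s"
        )
    else:
        score, rule = 1, f"turn {duration:.2f} s > {th.cond5_score2_max:g} s"
    return _result(5, score, None, rule, metrics={"turn_duration": duration})


def score_condition6(
    clearance: float | None, mean_speed: float, baseline: float,
    completed: bool, th: ScoringThresholds = ScoringThresholds(),
) -> ConditionResult:
    """Step Over Obstacle: clearance class plus a 75% speed floor.

    3 with high clearance at preserved speed, 2 with low clearance at
    preserved speed, 1 when crossing speed drops to 75% of baseline or
    below, 0 when the crossing was not completed.
    """
    if baseline <= 0:
        raise ValueError("baseline speed must be positive")
    if not completed:
        return _result(6, 0, None, "crossing not completed", completed=False)
    r = mean_speed / baseline
    metrics = {"clearance": clearance, "mean_speed": mean_speed,
               "baseline": baseline}
    if r <= th.cond6_speed_floor:
        return _result(
            6, 1, r, f"speed ratio {r:.3f} <= {th.cond6_speed_floor:.2f}",
            metrics=metrics,
        )
    if clearance is not None and clearance >= th.clearance_high:
        return _result(
            6, 3, r,
            f"high clearance {clearance:.3f} m >= {th.clearance_high:.2f} m, "
            f"speed ratio {r:.3f} > {th.cond6_speed_floor:.2f}",
            metrics=metrics,
        )
    return _result(
        6, 2, r,
        f"low clearance, speed ratio {r:.3f} > {th.cond6_speed_floor:.2f}",
        metrics=metrics,
    )


def detect_turn_duration(
    head_ap: ScalarSeries, head_spd: ScalarSeries,
    th: ScoringThresholds = ScoringThresholds(),
) -> tuple[float | None, bool]:
    """Bracket the pivot turn from head kinematics.

    The turn spans from the last instant forward head speed is at least
    +``turn_speed_threshold`` before the global AP-position maximum, to
    the first instant it is at or below the negative threshold after
    it. Returns ``(duration, completed)``; an incomplete turn (no
    interior maximum or missing crossing) gives ``(None, False)``.
    """
    pos = head_ap.values
    spd = head_spd.values
    if pos.size != spd.size:
        raise ValueError("position and speed series must share a grid")
    i_max = int(np.argmax(pos))
    if i_max <= 0 or i_max >= pos.size - 1:
        return None, False
    v = th.turn_speed_threshold
    before = np.flatnonzero(spd[:i_max] >= v)
    after = np.flatnonzero(spd[i_max:] <= -v)
    if before.size == 0 or after.size == 0:
        return None, False
    t = head_ap.times
    t_start = t[before[-1]]
    t_end = t[i_max + after[0]]
    return float(t_end - t_start), True


def _head_ap_series(traj: KeypointTrajectory) -> ScalarSeries:
    if all(k in traj.positions for k in MARKERLESS_HEAD):
        ap = np.mean([traj.positions[k][:, 0] for k in MARKERLESS_HEAD], axis=0)
    else:
        ap = traj.get("head", "turn detection")[:, 0]
    return ScalarSeries(traj.sample_rate, ap, t0=traj.t0, units="m")


@dataclass
class FGAReport:
    """Scored session: per-condition repetition results with provenance."""

    subject: dict
    thresholds: dict
    event_config: dict
    conditions: dict  # condition id -> {"repetitions": [...], "median_score": ...}
    software_version: str = SOFTWARE_VERSION
    created: str = ""

    def to_dict(self) -> dict:
        out = {
            "subject": self.subject,
            "software_version": self.software_version,
            "created": self.created,
            "thresholds": self.thresholds,
            "event_config": self.event_config,
            "conditions": {},
        }
        for cond, block in self.conditions.items():
            out["conditions"][str(cond)] = {
                "name": CONDITION_NAMES[int(cond)],
                "median_score": block["median_score"],
                "repetitions": [
                    {
                        "condition_id": r.condition_id,
                        "score": r.score,
                        "ratio_to_baseline": r.ratio_to_baseline,
                        "rule_fired": r.rule_fired,
                        "completed": r.completed,
                        "metrics": {
                            k: (None if v is None else float(v))
                            for k, v in r.metrics.items()
                        },
                    }
                    for r in block["repetitions"]
                ],
            }
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FGAReport":
        conditions = {}
        for cond, block in d["conditions"].items():
            reps = [
                ConditionResult(
                    condition_id=r["condition_id"],
                    score=r["score"],
                    ratio_to_baseline=r["ratio_to_baseline"],
                    rule_fired=r["rule_fired"],
                    completed=r["completed"],
                    metrics=r["metrics"],
                )
                for r in block["repetitions"]
            ]
            conditions[int(cond)] = {
                "median_score": block["median_score"],
                "repetitions": reps,
            }
        return cls(
            subject=d["subject"],
            thresholds=d["thresholds"],
            event_config=d["event_config"],
            conditions=conditions,
            software_version=d["software_version"],
            created=d["created"],
        )


def _median_score(reps: list[ConditionResult]) -> float | None:
    scores = [r.score for r in reps if r.score is not None]
    if not scores:
        return None
    return float(np.median(scores))


def _score_trial(cond: int, analysis: TrialAnalysis, traj: KeypointTrajectory,
                 baseline: float, baseline_max: float,
                 th: ScoringThresholds) -> ConditionResult:
    s = analysis.summary
    if cond == 2:
        res = score_condition2(s.mean_speed, baseline, th)
    elif cond in (3, 4):
        # maximum speed is compared against the baseline's maximum speed
        res = score_condition34(s.max_speed, baseline_max,
                                s.max_lateral_placement, th, condition_id=cond)
    elif cond == 5:
        head_ap = _head_ap_series(traj)
        duration, completed = detect_turn_duration(head_ap, analysis.head_spd, th)
        res = score_condition5(duration if completed else 0.0, completed, th)
        if completed:
            res.metrics["turn_duration"] = duration
    elif cond == 6:
        clearance = obstacle_clearance(analysis.apexes)
        completed = clearance is not None and s.n_steps >= 2
        res = score_condition6(clearance, s.mean_speed, baseline, completed, th)
    else:
        res = _result(cond, None, s.mean_speed / baseline,
                      "metrics only; no automated rule for this condition")
    res.metrics.update(
        duration=s.duration,
        mean_speed=s.mean_speed,
        max_speed=s.max_speed,
        distance_speed=s.distance_speed,
        n_steps=s.n_steps,
        max_lateral_placement=s.max_lateral_placement,
        max_step_width=s.max_step_width,
        mean_step_width=s.mean_step_width,
    )
    return res


def build_report(
    trials: dict[int, list[KeypointTrajectory]],
    th: ScoringThresholds = ScoringThresholds(),
    cfg: EventConfig = EventConfig(),
    subject: dict | None = None,
) -> FGAReport:
    """Score a full session of per-condition trials.

    ``trials`` maps condition id (1-10) to that condition's repetition
    trajectories (walkway frame). Condition 1 must be present: the
    median of its repetitions' mean bout speed is the baseline every
    other condition is scored against. A repetition whose analysis
    fails yields a flagged, unscored result rather than aborting the
    session.
    """
    if 1 not in trials or not trials[1]:
        raise ValueError("Condition 1 (baseline) trial is required")
    base_analyses = [analyze_trial(t, cfg) for t in trials[1]]
    baseline = float(np.median([a.summary.mean_speed for a in base_analyses]))
    baseline_max = float(np.median([a.summary.max_speed for a in base_analyses]))
    if baseline <= 0:
        raise ValueError("baseline mean speed must be positive")
    conditions = {}
    for cond in sorted(trials):
        reps = []
        for i, traj in enumerate(trials[cond]):
            try:
                analysis = (base_analyses[i] if cond == 1
                            else analyze_trial(traj, cfg))
                res = _score_trial(cond, analysis, traj, baseline,
                                   baseline_max, th)
            except FgaError as exc:
                res = _result(cond, None, None,
                              f"trial failed: {exc}", completed=False)
            reps.append(res)
        conditions[cond] = {
            "repetitions": reps,
            "median_score": _median_score(reps),
        }
    return FGAReport(
        subject=subject or {},
        thresholds=th.to_dict(),
        event_config=asdict(cfg),
        conditions=conditions,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
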