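"""FGA Condition 2-6 scoring rules, boundary conventions, turn
detection, and full-session report building."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fgakit import (
    FGAReport,
    GaitParams,
    ScoringThresholds,
    build_report,
    detect_turn_duration,
    head_speed,
    score_condition2,
    score_condition34,
    score_condition5,
    score_condition6,
    simulate_fga_session,
    simulate_pivot_trial,
    simulate_walk,
)
from fgakit.scoring import _head_ap_series

TH = ScoringThresholds()


@pytest.mark.parametrize(
    "ratio,score",
    [
        (1.30, 3),  # speed change greater than 125%
        (1.26, 3),
        (1.25, 2),  # shared endpoint belongs to the printed [110, 125] band
        (1.15, 2),
        (1.10, 2),
        (1.07, 1),
        (1.05, 1),
        (1.049, 0),
        (1.00, 0),  # no speed increase greater than 105%
        (0.90, 0),
    ],
)
def test_condition2_branches(ratio, score):
    res = score_condition2(ratio, 1.0, TH)
    assert res.score == score
    assert res.ratio_to_baseline == pytest.approx(ratio)


@pytest.mark.parametrize(
    "ratio,lateral,score",
    [
        (1.00, 0.0, 3),  # within [95, 105]%, clean lateral placement
        (0.95, 0.0, 3),
        (1.05, 0.0, 3),
        (0.92, 0.0, 2),
        (0.90, 0.0, 2),
        (1.10, 0.0, 2),
        (0.80, 0.0, 1),  # within [75, 90)%
        (0.75, 0.0, 1),
        (0.74, 0.0, 0),  # less than 75%
        (1.00, 0.20, 1),  # 0.0476 m beyond the limit caps the score at 1
        (1.20, 0.0, 1),  # above the 110% band: abnormal speed change
    ],
)
def test_condition34_branches(ratio, lateral, score):
    assert score_condition34(ratio, 1.0, lateral, TH).score == score


@pytest.mark.parametrize(
    "duration,completed,score",
    [
        (2.5, True, 3),  # turning in less than 3 s
        (2.99, True, 3),
        (3.0, True, 2),
        (4.0, True, 2),  # took longer than 3 s
        (4.5, True, 2),
        (5.0, True, 1),  # took longer than 4.5 s
        (0.0, False, 0),  # incomplete
    ],
)
def test_condition5_branches(duration, completed, score):
    assert score_condition5(duration, completed, TH).score == score


@pytest.mark.parametrize(
    "clearance,ratio,completed,score",
    [
        (0.15, 1.00, True, 3),  # high clearance, speed preserved
        (0.02, 1.00, True, 2),  # low clearance, speed preserved
        (0.02, 0.70, True, 1),  # speed below 75% of baseline
        (0.15, 0.70, True, 1),
        (None, 1.00, False, 0),  # incomplete crossing
    ],
)
def test_condition6_branches(clearance, ratio, completed, score):
    assert score_condition6(clearance, ratio, 1.0, completed, TH).score == score


def test_boundary_audit_every_endpoint_maps_to_one_score():
    """Each printed interval endpoint maps to exactly one score under
    the half-open convention (higher band owns the shared endpoint)."""
    cond2 = {1.05: 1, 1.10: 2, 1.25: 2}
    for r, expected in cond2.items():
        assert score_condition2(r, 1.0, TH).score == expected
    cond34 = {0.75: 1, 0.90: 2, 0.95: 3, 1.05: 3, 1.10: 2}
    for r, expected in cond34.items():
        assert score_condition34(r, 1.0, 0.0, TH).score == expected
    cond5 = {3.0: 2, 4.5: 2}
    for d, expected in cond5.items():
        assert score_condition5(d, True, TH).score == expected
    assert score_condition6(0.02, 0.75, 1.0, True, TH).score == 1
    assert score_condition6(0.10, 1.0, 1.0, True, TH).score == 3


@given(st.floats(min_value=0.2, max_value=2.0),
       st.floats(min_value=0.2, max_value=2.0))
def test_condition2_monotone_in_ratio(r1, r2):
    lo, hi = sorted([r1, r2])
    assert (score_condition2(lo, 1.0, TH).score
            <= score_condition2(hi, 1.0, TH).score)


def test_rule_fired_names_branch():
    res = score_condition2(1.30, 1.0, TH)
    assert "1.25" in res.rule_fired
    res = score_condition34(1.0, 1.0, 0.2, TH)
    assert "caps score at 1" in res.rule_fired


def test_nonpositive_baseline_rejected():
    with pytest.raises(ValueError):
        score_condition2(1.2, 0.0, TH)
    with pytest.raises(ValueError):
        score_condition34(1.0, -1.0, 0.0, TH)


@pytest.mark.parametrize("turn_duration,expected", [(2.5, 2.5), (4.0, 4.0)])
def test_turn_duration_measured_from_pivot(turn_duration, expected):
    p = GaitParams(walk_distance=4.2, noise_sd=0.0)
    traj, _ = simulate_pivot_trial(p, turn_duration)
    d, completed = detect_turn_duration(_head_ap_series(traj), head_speed(traj), TH)
    assert completed
    assert d == pytest.approx(expected, abs=0.2)


def test_monotone_walk_is_incomplete_turn(clean_walk):
    traj, _ = clean_walk
    d, completed = detect_turn_duration(_head_ap_series(traj), head_speed(traj), TH)
    assert not completed


def test_build_report_engineered_session():
    """A session engineered to hit the top branch of every scored
    condition yields (unscored, 3, 3, 3, 3, 3, unscored...)."""
    base = GaitParams(step_length=0.6, step_width=0.12, walk_distance=6.0,
                      noise_sd=0.0)
    session = simulate_fga_session(base, seed=5, turn_duration=2.5,
                                   obstacle_apex=0.25)
    trials = {c: [t for t, _ in trs] for c, trs in session.items()}
    report = build_report(trials)
    scores = {c: b["median_score"] for c, b in report.conditions.items()}
    assert scores[1] is None
    assert scores[2] == 3  # engineered speed ratio 1.30
    assert scores[3] == 3 and scores[4] == 3
    assert scores[5] == 3  # 2.5 s pivot
    assert scores[6] == 3  # 0.20 m clearance over the typical swing
    assert all(scores[c] is None for c in (7, 8, 9, 10))
    # thresholds are embedded for auditability
    assert report.thresholds["cond2_score3"] == 1.25


def test_report_json_roundtrip():
    base = GaitParams(noise_sd=0.0)
    session = simulate_fga_session(base, seed=2,
                                   speed_ratios={k: 1.0 for k in (2, 3, 4)})
    trials = {c: [t for t, _ in trs] for c, trs in session.items()
              if c in (1, 2)}
    report = build_report(trials)
    back = FGAReport.from_dict(json.loads(report.to_json()))
    assert back.to_dict() == report.to_dict()


def test_missing_baseline_rejected(clean_walk):
    traj, _ = clean_walk
    with pytest.raises(ValueError, match="Condition 1"):
        build_report({2: [traj]})


def test_three_repetitions_median():
    base = GaitParams(noise_sd=0.002, walk_distance=5.0)
    session = simulate_fga_session(base, seed=9, n_reps=3,
                                   speed_ratios={2: 1.30})
    trials = {c: [t for t, _ in trs] for c, trs in session.items()
              if c in (1, 2)}
    report = build_report(trials)
    block = report.conditions[2]
    assert len(block["repetitions"]) == 3
    scores = [r.score for r in block["repetitions"]]
    assert block["median_score"] == float(np.median(scores))
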