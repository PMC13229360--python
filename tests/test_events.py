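"""Stance/footstep/bout detection against simulator ground truth."""

import dataclasses

import numpy as np
import pytest

from fgakit import (
    EventConfig,
    GaitParams,
    LowConfidenceError,
    ScalarSeries,
    detect_bout,
    detect_stances,
    foot_speed,
    make_templates,
    normalized_xcorr,
    simulate_walk,
    sum_foot_speed,
)
from fgakit.events import check_alternation

CFG = EventConfig()


def test_stationary_foot_speed_near_zero():
    traj = _synthetic_translation(speed=0.0)
    v = foot_speed(traj, "left", CFG)
    assert np.max(v.values) < 1e-9


def test_translating_foot_speed_matches():
    traj = _synthetic_translation(speed=1.0)
    v = foot_speed(traj, "left", CFG)
    assert np.median(v.values[30:-30]) == pytest.approx(1.0, abs=0.01)


def _synthetic_translation(speed, fs=30.0, dur=6.0):
    from fgakit.io import KeypointTrajectory

    t = np.arange(int(dur * fs)) / fs
    ap = speed * t
    pos = np.column_stack([ap, np.zeros_like(t), np.zeros_like(t)])
    still = np.zeros((t.size, 3))
    return KeypointTrajectory(
        sample_rate=fs,
        positions={"left_heel": pos, "right_heel": still},
        frame_tag="walkway",
    )


def test_stance_speed_below_threshold(clean_walk):
    """During true stance the filtered foot speed stays below the
    0.15 m/s stance threshold (noiseless): the construction has zero
    stance velocity, and the ringing the 3 Hz zero-phase filter leaks
    between swing pulses must not break stance detection."""
    traj, gt = clean_walk
    t = traj.times
    for side in ("left", "right"):
        v = foot_speed(traj, side, CFG)
        for s, mid, _ in gt.footsteps:
            if s != side:
                continue
            mask = (t > mid - 0.06) & (t < mid + 0.06)
            assert np.max(v.values[mask]) < CFG.speed_threshold


def test_stance_count_and_midstance_times(clean_walk):
    traj, gt = clean_walk
    fs = traj.sample_rate
    all_stances = []
    for side in ("left", "right"):
        v = foot_speed(traj, side, CFG)
        all_stances.extend(detect_stances(v, traj, side, CFG))
    # keep stances born inside the bout (standing periods start at the
    # recording edges)
    inside = sorted(
        (s for s in all_stances if gt.bout_start - 0.25 <= s.start),
        key=lambda s: s.midstance_time,
    )
    assert len(inside) == len(gt.footsteps)
    # interior footsteps: midstance within one sample of ground truth
    for det, (side, mid, loc) in list(zip(inside, gt.footsteps))[:-2]:
        assert det.side == side
        assert det.midstance_time == pytest.approx(mid, abs=1.0 / fs)
        assert np.allclose(det.footstep_location[:2], loc[:2], atol=0.01)
    # last two stances merge with terminal quiet standing; their
    # locations are still exact
    for det, (side, mid, loc) in list(zip(inside, gt.footsteps))[-2:]:
        assert np.allclose(det.footstep_location[:2], loc[:2], atol=0.01)
        assert det.midstance_time == pytest.approx(mid, abs=3.0 / fs)


def test_constant_zero_speed_single_stance(clean_walk):
    traj, _ = clean_walk
    v = ScalarSeries(30.0, np.zeros(200))
    st = detect_stances(v, traj, "left", CFG)
    assert len(st) == 1
    assert st[0].start == 0.0
    assert st[0].end == pytest.approx(199 / 30)


def test_speed_above_threshold_no_stance(clean_walk):
    traj, _ = clean_walk
    v = ScalarSeries(30.0, np.full(200, 1.0))
    assert detect_stances(v, traj, "left", CFG) == []


def test_alternation_flagging():
    from fgakit.events import StanceInterval

    mk = lambda side, t: StanceInterval(side, t, t + 0.3, t + 0.15, [0, 0, 0])
    assert check_alternation([mk("left", 0), mk("right", 0.5), mk("left", 1.0)]) == []
    flags = check_alternation([mk("left", 0), mk("left", 0.5)])
    assert len(flags) == 1 and "left" in flags[0]


def test_templates_reversed_and_length():
    init, term = make_templates(cadence=2.0, steady_speed=1.2, fs=30.0)
    assert init.n == 45  # (0.5 + 2/cadence) s at 30 Hz
    assert np.allclose(term.values, init.values[::-1])


def test_template_peak_matches_generator_swing_peak():
    cadence, speed = 2.0, 1.2
    init, _ = make_templates(cadence, speed, fs=240.0)
    L = speed / cadence
    tau = 0.8 / cadence  # swing duration at stance fraction 0.6
    expected_peak = np.pi * L / tau  # raised-cosine swing advancing 2L
    assert init.values.max() == pytest.approx(expected_peak, rel=1e-3)


def test_bout_boundaries_match_ground_truth(clean_walk):
    traj, gt = clean_walk
    bout = detect_bout(sum_foot_speed(traj, CFG), CFG)
    fs = traj.sample_rate
    assert bout.t_start == pytest.approx(gt.bout_start, abs=2.0 / fs)
    assert bout.t_end == pytest.approx(gt.bout_end, abs=2.0 / fs)
    assert bout.corr_start > 0.95 and bout.corr_end > 0.95


def test_quiet_standing_low_confidence():
    v = ScalarSeries(30.0, np.random.default_rng(0).normal(0, 1e-4, 300))
    with pytest.raises(LowConfidenceError, match="initiation"):
        detect_bout(v, CFG)


def test_bout_shift_equivariance(clean_walk):
    """Padding k extra quiet samples in front shifts t_start by exactly
    k samples."""
    traj, _ = clean_walk
    s = sum_foot_speed(traj, CFG)
    b0 = detect_bout(s, CFG)
    for k in (7, 23):
        shifted = ScalarSeries(s.sample_rate,
                               np.concatenate([np.zeros(k), s.values]))
        bk = detect_bout(shifted, CFG)
        assert bk.t_start == pytest.approx(b0.t_start + k / s.sample_rate,
                                           abs=1e-9)
        assert bk.t_end == pytest.approx(b0.t_end + k / s.sample_rate, abs=1e-9)


def test_normalized_xcorr_against_bruteforce():
    rng = np.random.default_rng(3)
    x = rng.normal(size=200)
    tpl = rng.normal(size=40)
    r = normalized_xcorr(x, tpl)
    brute = np.array(
        [np.corrcoef(x[k:k + 40], tpl)[0, 1] for k in range(161)]
    )
    assert np.allclose(r, brute, atol=1e-12)
    assert int(np.argmax(r)) == int(np.argmax(brute))


@pytest.mark.parametrize("cadence", [1.5, 2.0, 2.5])
@pytest.mark.parametrize("step_length", [0.3, 0.55, 0.8])
def test_stance_count_grid(cadence, step_length):
    """Detected footstep count equals ground truth across the
    cadence x step-length grid (noiseless)."""
    p = GaitParams(step_length=step_length, cadence=cadence,
                   walk_distance=4.5, noise_sd=0.0, seed=0)
    traj, gt = simulate_walk(p)
    total = []
    for side in ("left", "right"):
        v = foot_speed(traj, side, CFG)
        total.extend(detect_stances(v, traj, side, CFG))
    inside = [s for s in total if s.start >= gt.bout_start - 0.25]
    assert len(inside) == len(gt.footsteps)
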