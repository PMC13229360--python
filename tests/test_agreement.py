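"""Two-system agreement: alignment oracle checks, registration,
closed-form regression and Bland-Altman values, step pairing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fgakit import (
    GaitParams,
    ScalarSeries,
    StanceInterval,
    bland_altman,
    ols_with_ci,
    pair_steps,
    simulate_two_systems,
    spatial_register,
    step_metrics,
    time_align,
)
from fgakit.events import sum_foot_speed


def test_time_align_identical_signals():
    rng = np.random.default_rng(0)
    v = np.abs(rng.normal(size=600))
    a = ScalarSeries(240.0, v)
    res = time_align(a, a)
    assert res.lag == 0.0
    assert res.peak_corr == pytest.approx(1.0)


def test_time_align_recovers_imposed_lag():
    p = GaitParams(walk_distance=4.0, noise_sd=0.0)
    ml, mk, gt = simulate_two_systems(p, lag=0.25, markerless_noise_sd=0.0)
    res = time_align(sum_foot_speed(ml), sum_foot_speed(mk))
    assert res.lag == pytest.approx(0.25, abs=1.0 / 240.0)


def test_time_align_equals_bruteforce_on_toy():
    """The implementation's argmax equals an exhaustive all-integer-
    shifts Pearson-correlation search on a 200-sample toy pair."""
    rng = np.random.default_rng(7)
    base = np.convolve(rng.normal(size=200), np.ones(9) / 9, mode="same")
    shift = 17
    a = np.roll(base, shift)
    sa = ScalarSeries(240.0, a)
    sb = ScalarSeries(240.0, base)
    res = time_align(sa, sb, max_lag=0.25)

    def corr(shift_k):
        if shift_k >= 0:
            x, y = a[shift_k:], base[: base.size - shift_k]
        else:
            x, y = a[:shift_k], base[-shift_k:]
        n = min(x.size, y.size)
        return np.corrcoef(x[:n], y[:n])[0, 1] if n > 8 else -np.inf

    ks = range(-60, 61)
    brute_k = max(ks, key=corr)
    assert res.lag * 240.0 == pytest.approx(brute_k)
    assert brute_k == shift


def test_spatial_register_constant_offset(clean_walk):
    traj, _ = clean_walk
    shifted = traj.translated([1.0, 2.0, 0.0])
    reg = spatial_register(traj, shifted)
    for k in traj.names:
        assert np.allclose(reg.positions[k], traj.positions[k], atol=1e-12)


def test_spatial_register_idempotent(clean_walk):
    traj, _ = clean_walk
    reg = spatial_register(traj, traj)
    for k in traj.names:
        assert np.allclose(reg.positions[k], traj.positions[k])


def test_ols_perfect_fit():
    x = np.arange(10, dtype=float)
    res = ols_with_ci(x, x)
    assert res.slope == pytest.approx(1.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope_ci[0] == pytest.approx(res.slope_ci[1], abs=1e-9)


def test_ols_affine():
    x = np.arange(10, dtype=float)
    res = ols_with_ci(x, 2 * x + 1)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)


def test_ols_textbook_triple():
    """x = (1,2,3), y = (1,2,4): closed-form OLS gives slope 3/2,
    intercept -2/3, R^2 = 27/28."""
    res = ols_with_ci([1, 2, 3], [1, 2, 4])
    assert res.slope == pytest.approx(1.5)
    assert res.intercept == pytest.approx(-2.0 / 3.0)
    assert res.r_squared == pytest.approx(27.0 / 28.0)
    assert res.slope_ci[0] < 1.5 < res.slope_ci[1]


def test_ols_constant_x_rejected():
    with pytest.raises(ValueError, match="constant"):
        ols_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bland_altman_identical():
    res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.mean_diff == 0.0
    assert res.loa_low == 0.0 and res.loa_high == 0.0


def test_bland_altman_constant_offset():
    a = np.array([0.5, 0.6, 0.7])
    res = bland_altman(a, a - 0.003)
    assert res.mean_diff == pytest.approx(0.003)
    assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)


def test_bland_altman_hand_computed():
    """Differences {-0.01, +0.01}: mean 0, sample SD 0.014142,
    limits of agreement ±0.027718."""
    res = bland_altman([0.0, 0.01], [0.01, 0.0])
    assert res.mean_diff == pytest.approx(0.0)
    sd = 0.02 / np.sqrt(2)  # 0.0141421
    assert res.loa_high == pytest.approx(1.96 * sd)
    assert res.loa_low == pytest.approx(-1.96 * sd)


@given(
    st.lists(st.floats(min_value=-1, max_value=1), min_size=2, max_size=20),
    st.integers(min_value=0, max_value=10**6),
)
def test_bland_altman_antisymmetric(a, seed):
    rng = np.random.default_rng(seed)
    b = rng.normal(size=len(a))
    fwd = bland_altman(a, b)
    rev = bland_altman(b, a)
    assert fwd.mean_diff == pytest.approx(-rev.mean_diff, abs=1e-12)
    assert fwd.loa_high == pytest.approx(-rev.loa_low, abs=1e-12)


def _steps_at(times):
    feet = [
        StanceInterval("left" if i % 2 == 0 else "right",
                       t - 0.2, t + 0.2, t, [0.5 * i, 0.05 * (-1) ** i, 0.0])
        for i, t in enumerate(times)
    ]
    return step_metrics(feet)


def test_pair_steps_identical_lists():
    s = _steps_at([1.0, 1.5, 2.0, 2.5])
    res = pair_steps(s, s)
    assert len(res.pairs) == len(s)
    assert not res.orphans_a and not res.orphans_b
    for a, b in res.pairs:
        assert a.step_length == b.step_length


def test_pair_steps_reports_orphan():
    s_full = _steps_at([1.0, 1.5, 2.0, 2.5])
    s_short = _steps_at([1.0, 1.5, 2.0])
    res = pair_steps(s_full, s_short)
    assert len(res.pairs) == len(s_short)
    assert len(res.orphans_a) == 1
    assert res.orphans_a[0].midstance_time == s_full[-1].midstance_time


def test_pair_steps_survives_time_jitter():
    rng = np.random.default_rng(1)
    times = np.arange(1.0, 4.0, 0.5)
    a = _steps_at(times)
    b = _steps_at(times + rng.uniform(-0.05, 0.05, size=times.size))
    res = pair_steps(a, b)
    assert len(res.pairs) == len(a)
    assert not res.orphans_a and not res.orphans_b


def test_end_to_end_two_system_recovery():
    """Noisy paired recordings (3 mm keypoint noise, 0.2 s lag) pooled
    over several trials recover near-unity step-length agreement."""
    L_ml, L_mk = [], []
    rng = np.random.default_rng(2024)
    from fgakit import extract_paired_trial

    for i in range(8):
        p = GaitParams(
            step_length=float(rng.uniform(0.4, 0.7)),
            step_width=0.10 if i % 2 == 0 else 0.25,
            walk_distance=4.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        ml, mk, _ = simulate_two_systems(p, lag=0.2, markerless_noise_sd=0.003)
        tr = extract_paired_trial(ml, mk)
        assert tr.alignment.lag == pytest.approx(0.2, abs=2.0 / 240.0)
        L_ml += list(tr.length_ml)
        L_mk += list(tr.length_mk)
    res = ols_with_ci(L_ml, L_mk)
    assert 0.97 <= res.slope <= 1.03
    assert abs(res.intercept) <= 0.01
    assert res.r_squared >= 0.95
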