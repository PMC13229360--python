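"""Two-system agreement machinery: temporal alignment, spatial
registration, paired-step matching, regression and Bland-Altman.

This reproduces the validation workflow for a markerless stream
recorded simultaneously with a marker-based reference: align the
clocks by maximizing the normalized cross-correlation of summed AP
foot speed (the markerless stream linearly interpolated up to the
markered rate first), register space by subtracting the initial left
foot position, match steps by midstance time, then quantify agreement
with ordinary least squares (markered regressed on markerless, 95%
t-based confidence intervals) and Bland-Altman limits of agreement
(mean markerless-minus-markered difference ± 1.96 sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import LowConfidenceError
from .io import KeypointTrajectory
from .signals import ScalarSeries, resample_linear
from .steps import StepRecord

__all__ = [
    "AlignmentResult",
    "RegressionResult",
    "BlandAltmanResult",
    "PairedSteps",
    "time_align",
    "spatial_register",
    "ols_with_ci",
    "bland_altman",
    "pair_steps",
]


@dataclass(frozen=True)
class AlignmentResult:
    lag: float  # s; markerless events occur this much later than markered
    peak_corr: float
    resampled_rate: float

    def __post_init__(self):
        if not -1.0 <= self.peak_corr <= 1.0:
            raise ValueError("peak correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    r_squared: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not self.loa_low <= self.mean_diff <= self.loa_high:
            raise ValueError("limits of agreement must bracket the mean")


def _overlap_corr(a: np.ndarray, b: np.ndarray, shift: int) -> float:
    """Pearson r between a[i] and b[i - shift] over their overlap."""
    if shift >= 0:
        seg_a, seg_b = a[shift:], b[: b.size - shift]
    else:
        seg_a, seg_b = a[: a.size + shift], b[-shift:]
    n = min(seg_a.size, seg_b.size)
    seg_a, seg_b = seg_a[:n], seg_b[:n]
    if n < 8:
        return -np.inf
    sa, sb = seg_a.std(), seg_b.std()
    if sa <= 0 or sb <= 0:
        return 0.0
    return float(np.corrcoef(seg_a, seg_b)[0, 1])


def time_align(
    markerless_sum_speed: ScalarSeries,
    markered_sum_speed: ScalarSeries,
    max_lag: float = 2.0,
) -> AlignmentResult:
    """Recover the markerless-relative-to-markered clock lag.

    The markerless summed foot speed is linearly interpolated to the
    markered sample rate; the lag maximizing the normalized (Pearson)
    cross-correlation over ±``max_lag`` seconds is returned. A positive
    lag means markerless events appear later on their own clock, so
    shifting the markerless time base by −lag aligns the streams.
    """
    rate = markered_sum_speed.sample_rate
    ml = resample_linear(markerless_sum_speed, rate)
    a = ml.values
    b = markered_sum_speed.values
    k_max = int(round(max_lag * rate))
    shifts = np.arange(-k_max, k_max + 1)
    corrs = np.array([_overlap_corr(a, b, int(s)) for s in shifts])
    best = int(np.argmax(corrs))
    peak = float(corrs[best])
    if not np.isfinite(peak) or peak < 0.5:
        raise LowConfidenceError(
            f"time alignment peak correlation {peak:.2f} below 0.5"
        )
    # lag includes any difference in the two streams' time origins
    lag = shifts[best] / rate + (markerless_sum_speed.t0 - markered_sum_speed.t0)
    return AlignmentResult(lag=float(lag), peak_corr=peak, resampled_rate=rate)


def spatial_register(
    traj_a: KeypointTrajectory, traj_b: KeypointTrajectory
) -> KeypointTrajectory:
    """Translate ``traj_b`` so both left feet coincide at the first sample."""
    def left_key(traj):
        for key in ("left_heel", "left_foot"):
            if key in traj.positions:
                return key
        traj.get("left_heel", "spatial registration")

    pa = traj_a.get(left_key(traj_a))[0]
    pb = traj_b.get(left_key(traj_b))[0]
    return traj_b.translated(pa - pb)


def ols_with_ci(x, y, confidence: float = 0.95) -> RegressionResult:
    """OLS of y on x with t-based confidence intervals on both
    coefficients and the squared Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate fit")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1.0 - confidence)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Mean difference (a − b) and 95% limits of agreement.

    The limits use the sample SD (n−1 denominator) and a fixed 1.96
    multiplier, the conventional 95% band.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        loa_low=mean - loa_multiplier * sd,
        loa_high=mean + loa_multiplier * sd,
        n=int(a.size),
    )


@dataclass
class PairedSteps:
    pairs: list  # (StepRecord_a, StepRecord_b)
    orphans_a: list
    orphans_b: list


def pair_steps(
    steps_a: list[StepRecord], steps_b: list[StepRecord],
    max_time_gap: float = 0.3,
) -> PairedSteps:
    """Greedy nearest-midstance-time matching of two step lists.

    Candidate pairs are taken closest-first; each step matches at most
    once and only within ``max_time_gap`` seconds. Unmatched steps are
    returned, never silently dropped.
    """
    cands = [
        (abs(a.midstance_time - b.midstance_time), i, j)
        for i, a in enumerate(steps_a)
        for j, b in enumerate(steps_b)
        if abs(a.midstance_time - b.midstance_time) <= max_time_gap
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((steps_a[i], steps_b[j]))
    pairs.sort(key=lambda p: p[0].midstance_time)
    return PairedSteps(
        pairs=pairs,
        orphans_a=[a for i, a in enumerate(steps_a) if i not in used_a],
        orphans_b=[b for j, b in enumerate(steps_b) if j not in used_b],
    )
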