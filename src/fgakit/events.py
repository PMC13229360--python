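"""Stance, footstep and walking-bout detection from foot-speed signals.

The detection chain follows the velocity-threshold approach standard in
markerless gait analysis: the anterior-posterior heel speed is low-pass
filtered at 3 Hz; regions where it stays below 0.15 m/s are stance
phases; the temporal middle of each stance is the midstance instant and
the mean heel position over the stance is the footstep location. Bout
boundaries come from normalized cross-correlation of the summed
left+right foot speed against gait-initiation / gait-termination
templates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LowConfidenceError
from .io import KeypointTrajectory
from .signals import ScalarSeries, derivative, lowpass

__all__ = [
    "EventConfig",
    "StanceInterval",
    "BoutWindow",
    "foot_speed",
    "sum_foot_speed",
    "detect_stances",
    "make_templates",
    "detect_bout",
    "normalized_xcorr",
    "check_alternation",
]


@dataclass(frozen=True)
class EventConfig:
    """Tunable constants of event detection.

    Defaults are the protocol constants: stance when foot speed is
    below 0.15 m/s after a 3 Hz low-pass. The debouncing windows
    (``min_stance``, ``min_swing_gap``) are far below the stance and
    swing durations of ordinary walking (~0.6 s and ~0.4 s at cadence
    2); the template parameters describe the gait the initiation /
    termination templates are synthesized for.
    """

    speed_threshold: float = 0.15  # m/s
    foot_speed_cutoff: float = 3.0  # Hz
    min_stance: float = 0.15  # s, shorter sub-threshold runs are noise
    min_swing_gap: float = 0.10  # s, shorter above-threshold blips are merged
    template_cadence: float = 2.0  # steps/s
    template_speed: float = 1.2  # m/s
    template_stance_fraction: float = 0.6
    min_peak_corr: float = 0.5  # bout detection confidence floor
    footstep_position: str = "stance_mean"  # or "midpoint"
    speed_axis: str = "ap"  # or "3d"

    def __post_init__(self):
        for name in ("speed_threshold", "foot_speed_cutoff", "min_stance",
                     "min_swing_gap", "template_cadence", "template_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StanceInterval:
    side: str
    start: float
    end: float
    midstance_time: float
    footstep_location: np.ndarray

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("stance must have start < end")
        if not self.start <= self.midstance_time <= self.end:
            raise ValueError("midstance must lie inside the stance")
        object.__setattr__(
            self, "footstep_location",
            np.asarray(self.footstep_location, float).reshape(3),
        )


@dataclass(frozen=True)
class BoutWindow:
    t_start: float
    t_end: float
    corr_start: float
    corr_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("bout must have t_start < t_end")


def _heel_key(traj: KeypointTrajectory, side: str) -> str:
    for suffix in ("heel", "foot"):
        if f"{side}_{suffix}" in traj.positions:
            return f"{side}_{suffix}"
    # raise the named-keypoint error for the markerless name
    traj.get(f"{side}_heel", "foot_speed")


def foot_speed(traj: KeypointTrajectory, side: str,
               cfg: EventConfig = EventConfig()) -> ScalarSeries:
    """Low-passed absolute AP heel speed of one foot (m/s, >= 0)."""
    key = _heel_key(traj, side)
    if cfg.speed_axis == "3d":
        pos = traj.get(key)
        v = np.gradient(pos, 1.0 / traj.sample_rate, axis=0)
        raw = ScalarSeries(traj.sample_rate, np.linalg.norm(v, axis=1),
                           t0=traj.t0, units="m/s")
        return lowpass(raw, cfg.foot_speed_cutoff)
    ap = traj.axis_series(key, axis=0)
    v = lowpass(derivative(ap), cfg.foot_speed_cutoff)
    return ScalarSeries(v.sample_rate, np.abs(v.values), t0=v.t0, units="m/s")


def sum_foot_speed(traj: KeypointTrajectory,
                   cfg: EventConfig = EventConfig()) -> ScalarSeries:
    """|left| + |right| AP foot speed, the bout-detection signal."""
    l = foot_speed(traj, "left", cfg)
    r = foot_speed(traj, "right", cfg)
    return ScalarSeries(l.sample_rate, l.values + r.values, t0=l.t0, units="m/s")


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def detect_stances(speed: ScalarSeries, traj: KeypointTrajectory, side: str,
                   cfg: EventConfig = EventConfig()) -> list[StanceInterval]:
    """Maximal sub-threshold regions of one foot's speed signal.

    Above-threshold gaps shorter than ``min_swing_gap`` are merged into
    the surrounding stance; merged regions shorter than ``min_stance``
    are discarded. Returns an empty list when no stance is found.
    """
    below = speed.values < cfg.speed_threshold
    if not below.any():
        return []
    runs = _runs(below)
    # merge across short above-threshold blips
    min_gap = int(round(cfg.min_swing_gap * speed.sample_rate))
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < min_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = int(round(cfg.min_stance * speed.sample_rate))
    key = _heel_key(traj, side)
    pos = traj.get(key)
    t = speed.times
    out = []
    for start, stop in merged:
        if stop - start < max(min_len, 2):
            continue
        t_a, t_b = float(t[start]), float(t[stop - 1])
        if cfg.footstep_position == "midpoint":
            loc = pos[(start + stop - 1) // 2]
        else:
            loc = pos[start:stop].mean(axis=0)
        out.append(
            StanceInterval(side=side, start=t_a, end=t_b,
                           midstance_time=0.5 * (t_a + t_b),
                           footstep_location=loc)
        )
    return out


def make_templates(cadence: float, steady_speed: float, fs: float,
                   stance_fraction: float = 0.6, lead_in: float = 0.5,
                   lowpass_cutoff: float | None = None):
    """Gait-initiation and gait-termination templates.

    The initiation template is the closed-form summed |AP| foot-speed
    profile of a two-step gait start: a quiet plateau of ``lead_in``
    seconds followed by the first two swing-speed pulses at full
    amplitude (raised-cosine swings, each advancing two step lengths,
    one step period apart). Total length ``lead_in + 2/cadence``
    seconds. The termination template is its time-reverse. When
    ``lowpass_cutoff`` is given, both templates are filtered exactly as
    the measured foot-speed signals are, so matched filtering compares
    like with like.
    """
    if cadence <= 0 or steady_speed <= 0 or fs <= 0:
        raise ValueError("template parameters must be positive")
    step_length = steady_speed / cadence
    T = 1.0 / cadence
    tau = 2.0 * (1.0 - stance_fraction) * T
    n = int(round((lead_in + 2.0 * T) * fs))
    t = np.arange(n) / fs
    peak = np.pi * step_length / tau  # peak of a 2L raised-cosine swing
    vals = np.zeros(n)
    for onset in (lead_in, lead_in + T):
        u = (t - onset) / tau
        inside = (u > 0) & (u < 1)
        vals = np.where(inside, vals + peak * np.sin(np.pi * np.clip(u, 0, 1)),
                        vals)
    init = ScalarSeries(fs, vals, units="m/s")
    if lowpass_cutoff is not None:
        init = ScalarSeries(fs, np.maximum(lowpass(init, lowpass_cutoff).values,
                                           0.0), units="m/s")
    term = ScalarSeries(fs, init.values[::-1].copy(), units="m/s")
    return init, term


def normalized_xcorr(signal: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of the template with every signal window.

    Valid-mode: output[k] correlates ``template`` with
    ``signal[k : k+len(template)]``. Windows with (near-)zero variance
    score 0.
    """
    x = np.asarray(signal, float)
    tpl = np.asarray(template, float)
    m = tpl.size
    if x.size < m:
        raise ValueError("signal shorter than template")
    tpl0 = tpl - tpl.mean()
    tpl_ss = float(tpl0 @ tpl0)
    if tpl_ss <= 0:
        raise ValueError("template is constant")
    win = np.lib.stride_tricks.sliding_window_view(x, m)
    wmean = win.mean(axis=1)
    num = win @ tpl0  # window means cancel against the zero-mean template
    wss = (win**2).sum(axis=1) - m * wmean**2
    denom = np.sqrt(np.maximum(wss, 0.0) * tpl_ss)
    scale = max(float(np.ptp(x)), 1e-12)
    good = denom > 1e-9 * scale * np.sqrt(tpl_ss)
    out = np.zeros(win.shape[0])
    out[good] = num[good] / denom[good]
    return np.clip(out, -1.0, 1.0)


def detect_bout(sum_speed: ScalarSeries, cfg: EventConfig = EventConfig(),
                templates=None) -> BoutWindow:
    """Locate the walking bout via template cross-correlation.

    ``t_start`` is the lag maximizing normalized cross-correlation with
    the initiation template, reported at the template's first swing
    onset; ``t_end`` likewise with the termination template at its last
    swing offset, searched after ``t_start``. A peak correlation below
    ``cfg.min_peak_corr`` raises :class:`LowConfidenceError` naming the
    failing template.
    """
    fs = sum_speed.sample_rate
    if templates is None:
        templates = make_templates(
            cfg.template_cadence, cfg.template_speed, fs,
            stance_fraction=cfg.template_stance_fraction,
            lowpass_cutoff=cfg.foot_speed_cutoff,
        )
    init, term = templates
    lead_in_s = 0.5  # template lead-in used by make_templates
    r_init = normalized_xcorr(sum_speed.values, init.values)
    k0 = int(np.argmax(r_init))
    corr_start = float(r_init[k0])
    if corr_start < cfg.min_peak_corr:
        raise LowConfidenceError(
            f"gait-initiation template peak correlation {corr_start:.2f} "
            f"below {cfg.min_peak_corr}"
        )
    t_start = sum_speed.t0 + (k0 + round(lead_in_s * fs)) / fs

    r_term = normalized_xcorr(sum_speed.values, term.values)
    # last swing offset sits lead_in before the end of the reversed template
    off = term.values.size - round(lead_in_s * fs)
    k_min = max(k0 + 1, 0)
    if k_min >= r_term.size:
        raise LowConfidenceError("no room for a termination after the start")
    r_term_view = r_term.copy()
    r_term_view[:k_min] = -np.inf
    k1 = int(np.argmax(r_term_view))
    corr_end = float(r_term[k1])
    if corr_end < cfg.min_peak_corr:
        raise LowConfidenceError(
            f"gait-termination template peak correlation {corr_end:.2f} "
            f"below {cfg.min_peak_corr}"
        )
    t_end = sum_speed.t0 + (k1 + off) / fs
    if t_end <= t_start:
        raise LowConfidenceError("termination found before initiation")
    return BoutWindow(t_start=float(t_start), t_end=float(t_end),
                      corr_start=corr_start, corr_end=corr_end)


def check_alternation(stances: list[StanceInterval]) -> list[str]:
    """Data-quality flags for non-alternating left/right footsteps."""
    flags = []
    ordered = sorted(stances, key=lambda s: s.midstance_time)
    for a, b in zip(ordered, ordered[1:]):
        if a.side == b.side:
            flags.append(
                f"consecutive {a.side} footsteps at t={a.midstance_time:.2f}s "
                f"and t={b.midstance_time:.2f}s (missed contralateral step?)"
            )
    return flags
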