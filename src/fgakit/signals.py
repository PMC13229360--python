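"""Uniformly sampled scalar series and the filtering/differentiation
primitives used throughout the gait pipeline.

All filtering is zero-phase (forward-backward Butterworth) so event
timing derived from filtered signals carries no phase lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = ["ScalarSeries", "lowpass", "derivative", "resample_linear"]

#: requested cutoffs at or above this fraction of Nyquist are clamped
NYQUIST_GUARD = 0.9

#: Butterworth order used for every low-pass in the pipeline
FILTER_ORDER = 4


@dataclass(frozen=True)
class ScalarSeries:
    """A uniformly sampled real-valued time series."""

    sample_rate: float
    values: np.ndarray
    t0: float = 0.0
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    @property
    def duration(self) -> float:
        return max(self.n - 1, 0) / self.sample_rate

    def slice_time(self, t_start: float, t_end: float) -> "ScalarSeries":
        """Sub-series covering [t_start, t_end] (inclusive of boundary samples)."""
        t = self.times
        mask = (t >= t_start - 0.5 / self.sample_rate) & (
            t <= t_end + 0.5 / self.sample_rate
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError("time window outside series span")
        return replace(self, values=self.values[idx], t0=float(t[idx[0]]))


def lowpass(s: ScalarSeries, cutoff: float) -> ScalarSeries:
    """Zero-phase 4th-order Butterworth low-pass.

    The forward-backward pass doubles the effective order (~8th-order
    roll-off) and cancels phase, so symmetric pulses keep their peak
    sample. DC gain is exactly 1. Cutoffs at or above 90% of Nyquist are
    clamped with a warning: such a filter is unrealizable/ill-conditioned
    at the given sample rate.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nyq = s.sample_rate / 2.0
    if cutoff >= NYQUIST_GUARD * nyq:
        warnings.warn(
            f"cutoff {cutoff:g} Hz >= {NYQUIST_GUARD:.0%} of Nyquist "
            f"({nyq:g} Hz); clamping",
            stacklevel=2,
        )
        cutoff = NYQUIST_GUARD * nyq
    b, a = sps.butter(FILTER_ORDER, cutoff / nyq)
    padlen = 3 * max(len(a), len(b))  # scipy's default warm-up
    if s.n <= padlen:
        raise ValueError(
            f"series of {s.n} samples too short for filter warm-up ({padlen})"
        )
    return replace(s, values=sps.filtfilt(b, a, s.values))


def derivative(s: ScalarSeries) -> ScalarSeries:
    """Finite-difference time derivative.

    Central differences in the interior (exact for quadratics), one-sided
    first-order at the two ends. Units gain a "/s".
    """
    if s.n < 3:
        raise ValueError("derivative needs at least 3 samples")
    dv = np.gradient(s.values, 1.0 / s.sample_rate)
    units = f"{s.units}/s" if s.units else "1/s"
    return replace(s, values=dv, units=units)


def resample_linear(s: ScalarSeries, new_rate: float) -> ScalarSeries:
    """Linear-interpolation resampling onto a grid at ``new_rate``.

    The new grid starts at ``t0`` and covers the original span; the first
    sample is preserved exactly, and any original sample instant that
    falls on the new grid is reproduced exactly.
    """
    if new_rate <= 0:
        raise ValueError("new_rate must be positive")
    if s.n == 0:
        raise ValueError("cannot resample an empty series")
    t_old = s.times
    n_new = int(np.floor(s.duration * new_rate)) + 1
    t_new = s.t0 + np.arange(n_new) / new_rate
    return ScalarSeries(
        sample_rate=new_rate,
        values=np.interp(t_new, t_old, s.values),
        t0=s.t0,
        units=s.units,
    )
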