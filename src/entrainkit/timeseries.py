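"""Continuous-series representation of step trains and correlation analyses.

Discrete footfall onsets are converted to a uniformly sampled pulse series
(default 100 Hz, a unit impulse at the sample nearest each onset), optionally
smoothed with a zero-phase Butterworth low-pass, and analysed by normalized
auto-/cross-correlation: the autocorrelation maximum inside a physiological
lag window estimates the stepping period (tempo), and the cross-correlation
maximum between the two walkers' series estimates their mutual lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .event_io import ValidationError


@dataclass
class PulseSeries:
    """A uniformly sampled series: ``values[i]`` at time ``t0 + i / rate``."""

    values: np.ndarray
    rate: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.values.size < 1:
            raise ValueError("series must have at least one sample")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate


@dataclass
class CorrelationProfile:
    """A correlation-vs-lag curve with its peak location."""

    lags: np.ndarray
    values: np.ndarray
    peak_lag: float
    peak_value: float

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.lags, self.values]),
            fmt="%.6f",
            delimiter="\t",
            header="lag_s\tcorrelation",
            comments="",
        )


def events_to_series(
    onsets,
    rate: float = 100.0,
    span: tuple[float, float] | None = None,
) -> PulseSeries:
    """Place a unit impulse at the sample nearest each onset.

    ``span`` is the [start, end] interval covered by the series; it defaults
    to [first onset, last onset].  Two onsets rounding to the same sample are
    physically impossible steps and raise :class:`ValidationError`.
    """
    onsets = np.asarray(onsets, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if span is None:
        if onsets.size == 0:
            raise ValueError("span required for empty onset list")
        span = (float(onsets.min()), float(onsets.max()))
    start, end = float(span[0]), float(span[1])
    if end < start:
        raise ValueError("span end must be >= start")
    n = int(round((end - start) * rate)) + 1
    values = np.zeros(n)
    if onsets.size:
        if onsets.min() < start - 0.5 / rate or onsets.max() > end + 0.5 / rate:
            raise ValueError("onset outside span")
        idx = np.round((onsets - start) * rate).astype(int)
        idx = np.clip(idx, 0, n - 1)
        if np.unique(idx).size != idx.size:
            raise ValidationError(
                "two onsets round to the same sample; raise the rate or check "
                "the annotations"
            )
        values[idx] = 1.0
    return PulseSeries(values, rate=rate, t0=start)


def smooth(series: PulseSeries, order: int = 3, cutoff: float = 4.0) -> PulseSeries:
    """Zero-phase (forward-backward) low-pass Butterworth filtering.

    Being non-causal, the filter leaves event peaks where they are: a pure
    impulse maps to a symmetric kernel centred on the impulse.  Edges use
    reflect padding of three times the filter order.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = series.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    b, a = signal.butter(order, cutoff, btype="low", fs=series.rate)
    padlen = min(3 * order, len(series) - 1)
    values = signal.filtfilt(b, a, series.values, padtype="even", padlen=padlen)
    return PulseSeries(values, rate=series.rate, t0=series.t0)


def autocorrelation(series: PulseSeries, max_lag: float | None = None) -> CorrelationProfile:
    """Normalized autocorrelation (biased estimator), lag 0 .. ``max_lag``.

    The series is demeaned and the profile normalized so the lag-0 value is
    exactly 1; values lie in [-1, 1].
    """
    x = series.values - series.values.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0:
        raise ValidationError("constant series has undefined autocorrelation")
    full = signal.correlate(x, x, mode="full", method="auto")[n - 1 :]
    ac = full / denom
    lags = np.arange(n) / series.rate
    if max_lag is not None:
        if max_lag >= series.duration:
            raise ValueError("max_lag must be shorter than the series")
        keep = lags <= max_lag + 0.5 / series.rate
        lags, ac = lags[keep], ac[keep]
    k = int(np.argmax(ac))
    return CorrelationProfile(lags, ac, float(lags[k]), float(ac[k]))


def autocorrelation_period(
    series: PulseSeries,
    window: tuple[float, float] = (0.5, 1.5),
) -> tuple[float, CorrelationProfile]:
    """Stepping period = lag of the autocorrelation maximum inside ``window``.

    The default window (0.5-1.5 s) brackets plausible bipedal step periods;
    a train of period T < 0.5 s is reported at its first harmonic inside the
    window.  Ties are broken toward the smaller lag.
    """
    lo, hi = window
    if hi >= series.duration:
        raise ValueError(
            f"autocorrelation window upper edge {hi} s exceeds series "
            f"duration {series.duration:.2f} s"
        )
    profile = autocorrelation(series)
    keep = (profile.lags >= lo - 1e-12) & (profile.lags <= hi + 1e-12)
    if not np.any(keep):
        raise ValueError("window contains no lags at this rate")
    lags, vals = profile.lags[keep], profile.values[keep]
    k = int(np.argmax(vals))  # argmax takes the first (smallest-lag) maximum
    period = float(lags[k])
    return period, CorrelationProfile(lags, vals, period, float(vals[k]))


def _pearson_at_lag(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Pearson correlation of the overlapping segments of a and b at lag k
    samples (positive k: b trails a)."""
    if k >= 0:
        x, y = a[: a.size - k], b[k:]
    else:
        x, y = a[-k:], b[: b.size + k]
    if x.size < 3:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def cross_correlation_lag(
    a: PulseSeries,
    b: PulseSeries,
    max_lag: float = 0.5,
    increment: float = 1.0 / 24.0,
) -> tuple[float, CorrelationProfile]:
    """Between-walker lag = argmax of the normalized cross-correlation.

    Correlation is computed at the native sample resolution, then restricted
    to the ``increment`` grid (default 1/24 s) by nearest native lag; positive
    lag means ``b`` (hind walker) trails ``a`` (front walker).  Ties are
    broken toward the smallest absolute lag, and an exact +/-L tie toward the
    nonnegative lag.
    """
    if a.rate != b.rate:
        raise ValueError("series must share the sampling rate")
    if len(a) != len(b):
        raise ValueError("series must share the span (equal lengths)")
    rate = a.rate
    kmax = int(round(max_lag * rate))
    if kmax >= len(a):
        raise ValueError("max_lag must be shorter than the series")
    native_k = np.arange(-kmax, kmax + 1)
    native_r = np.array([_pearson_at_lag(a.values, b.values, int(k)) for k in native_k])

    n_steps = int(np.floor(max_lag / increment + 1e-9))
    grid = np.arange(-n_steps, n_steps + 1) * increment
    grid_k = np.round(grid * rate).astype(int)
    grid_r = native_r[grid_k + kmax]

    finite = np.isfinite(grid_r)
    if not np.any(finite):
        raise ValidationError("cross-correlation undefined (constant overlap)")
    best = np.nanmax(grid_r)
    at_best = np.where(finite & (grid_r >= best - 1e-12))[0]
    # smallest |lag| wins; symmetric tie resolved toward the nonnegative lag
    order = sorted(at_best, key=lambda i: (abs(grid[i]), grid[i] < 0))
    j = order[0]
    return float(grid[j]), CorrelationProfile(grid, grid_r, float(grid[j]), float(grid_r[j]))
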