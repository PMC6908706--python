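"""Per-bout pacemaker (leadership) inference via Granger causality.

The two walkers' smoothed pulse series are modelled as a bivariate vector
autoregression (VAR) fit by ordinary least squares, one equation per series.
The lag order is chosen by the Akaike information criterion over a grid of
1..max samples (the spec grid "0 to 0.3 s" at 100 Hz).  For each direction,
an F test of the joint nullity of the cross-lag coefficients (restricted
vs. full OLS fit) decides whether one series predicts the other beyond its
own past; bouts are then classified front-leads / hind-leads / bidirectional
/ none at a significance level alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .timeseries import PulseSeries


class DegenerateSeriesError(ValueError):
    """The design matrix is singular (e.g. a constant series)."""


CLASS_FRONT = "front_leads"
CLASS_HIND = "hind_leads"
CLASS_BOTH = "bidirectional"
CLASS_NONE = "none"


@dataclass
class VARFit:
    """OLS fit of a bivariate VAR(p): one equation per series.

    ``coefs[i]`` holds equation i's parameters ordered
    [intercept, a_lag1..a_lagp, b_lag1..b_lagp].
    """

    p: int
    coefs: np.ndarray           # (2, 1 + 2p)
    residuals: np.ndarray       # (n_used, 2)
    rss: np.ndarray             # (2,)
    sigma_u: np.ndarray         # (2, 2) residual covariance (MLE)
    n_used: int

    @property
    def aic(self) -> float:
        """ln det(Sigma_u) + 2 k / n with k = total estimated parameters."""
        sign, logdet = np.linalg.slogdet(self.sigma_u)
        if sign <= 0:
            return -math.inf
        k = 2 * (1 + 2 * self.p)
        return float(logdet + 2.0 * k / self.n_used)


@dataclass
class LagSelection:
    candidate_lags: np.ndarray  # seconds
    aic: np.ndarray
    optimal_lag: float          # seconds
    rate: float

    @property
    def optimal_order(self) -> int:
        return int(round(self.optimal_lag * self.rate))


@dataclass
class GrangerResult:
    bout_id: str | None
    p_front_to_hind: float
    p_hind_to_front: float
    stat_f2h: float
    stat_h2f: float
    lag_used: float             # seconds
    classification: str
    n_samples: int = 0
    flags: list[str] = field(default_factory=list)


def _values(x) -> tuple[np.ndarray, float]:
    if isinstance(x, PulseSeries):
        return x.values, x.rate
    return np.asarray(x, dtype=float), 100.0


def _lag_matrix(a: np.ndarray, b: np.ndarray, p: int, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Design (intercept + p lags of a + p lags of b) and response rows
    ``start..n-1``; ``start >= p`` fixes a common estimation sample across
    candidate orders."""
    n = a.size
    rows = n - start
    X = np.empty((rows, 1 + 2 * p))
    X[:, 0] = 1.0
    for j in range(1, p + 1):
        X[:, j] = a[start - j : n - j]
        X[:, p + j] = b[start - j : n - j]
    Y = np.column_stack([a[start:], b[start:]])
    return X, Y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, float(resid @ resid)


def fit_var(a, b, p: int, start: int | None = None) -> VARFit:
    """Fit a bivariate VAR(p) by OLS (equation-by-equation).

    Raises :class:`DegenerateSeriesError` when either series is constant over
    the estimation sample (singular design).
    """
    av, _ = _values(a)
    bv, _ = _values(b)
    if av.size != bv.size:
        raise ValueError("series must have equal length")
    if p < 1:
        raise ValueError("VAR order must be >= 1")
    start = p if start is None else max(start, p)
    n_used = av.size - start
    if n_used <= 2 * (1 + 2 * p):
        raise ValueError(
            f"series too short for VAR({p}): {n_used} usable rows"
        )
    if np.ptp(av[start - p:]) == 0 or np.ptp(bv[start - p:]) == 0:
        raise DegenerateSeriesError("constant series gives a singular design")
    X, Y = _lag_matrix(av, bv, p, start)
    coefs = np.empty((2, X.shape[1]))
    resid = np.empty_like(Y)
    rss = np.empty(2)
    for i in range(2):
        coefs[i], resid[:, i], rss[i] = _ols(X, Y[:, i])
    sigma_u = resid.T @ resid / n_used
    return VARFit(p=p, coefs=coefs, residuals=resid, rss=rss, sigma_u=sigma_u, n_used=n_used)


def select_lag(a, b, max_lag: float = 0.3, rate: float | None = None) -> LagSelection:
    """AIC lag-order selection on a common estimation sample.

    Candidate orders are 1..round(max_lag * rate) samples; every candidate is
    fit on the rows left after dropping max-order presample values, so the
    AICs are comparable.  Ties go to the smaller order.  A series too short
    for the full grid truncates the grid (recorded, not fatal).
    """
    av, ra = _values(a)
    bv, rb = _values(b)
    if isinstance(a, PulseSeries) and isinstance(b, PulseSeries) and ra != rb:
        raise ValueError("series must share the sampling rate")
    rate = ra if rate is None else rate
    p_max = int(round(max_lag * rate))
    if p_max < 1:
        raise ValueError("max_lag shorter than one sample")
    # largest order the sample can support on a common estimation window
    while p_max > 1 and av.size - p_max <= 2 * (1 + 2 * p_max):
        p_max -= 1
    if av.size - p_max <= 2 * (1 + 2 * p_max):
        raise ValueError("series too short for any VAR order")
    orders = np.arange(1, p_max + 1)
    aics = np.array([fit_var(av, bv, int(p), start=p_max).aic for p in orders])
    best = int(orders[int(np.argmin(aics))])  # argmin takes first == smaller p
    return LagSelection(orders / rate, aics, best / rate, rate)


def select_lag_global(pairs, max_lag: float = 0.3, rate: float = 100.0) -> LagSelection:
    """Single lag order minimizing the summed AIC over many bouts.

    ``pairs`` is an iterable of (front, hind) series; bouts too short for a
    candidate order simply do not contribute to that order's sum (their own
    truncated grids still contribute where defined).
    """
    p_max = int(round(max_lag * rate))
    totals = np.zeros(p_max)
    counts = np.zeros(p_max, dtype=int)
    for a, b in pairs:
        try:
            sel = select_lag(a, b, max_lag=max_lag, rate=rate)
        except (ValueError, DegenerateSeriesError):
            continue
        k = sel.aic.size
        totals[:k] += sel.aic
        counts[:k] += 1
    valid = counts == counts.max()
    if counts.max() == 0:
        raise ValueError("no bout long enough for lag selection")
    # compare orders only where every contributing bout is represented
    mean_aic = np.where(valid, totals / np.maximum(counts, 1), np.inf)
    best = int(np.argmin(mean_aic)) + 1
    return LagSelection(np.arange(1, p_max + 1) / rate, mean_aic, best / rate, rate)


def granger_f(a: np.ndarray, b: np.ndarray, p: int, direction: str) -> tuple[float, float, int]:
    """F test that the cross-lags are jointly zero in one VAR equation.

    ``direction='f2h'`` tests whether a (front) predicts b (hind): equation
    for b, restricted model = own lags only.  Returns (F, p-value, df_denom).
    """
    n = a.size
    start = p
    n_used = n - start
    own, cross = (b, a) if direction == "f2h" else (a, b)
    y = own[start:]
    # canonical column order [1, own lags, cross lags]: swapping the input
    # series then swaps the two directional tests bit-for-bit
    X_full = np.empty((n_used, 1 + 2 * p))
    X_full[:, 0] = 1.0
    for j in range(1, p + 1):
        X_full[:, j] = own[start - j : n - j]
        X_full[:, p + j] = cross[start - j : n - j]
    X_r = X_full[:, : 1 + p]
    _, _, rss_f = _ols(X_full, y)
    _, _, rss_r = _ols(X_r, y)
    df_denom = n_used - (1 + 2 * p)
    if df_denom <= 0 or rss_f <= 0:
        return math.nan, math.nan, df_denom
    F = ((rss_r - rss_f) / p) / (rss_f / df_denom)
    F = max(F, 0.0)
    return float(F), float(stats.f.sf(F, p, df_denom)), df_denom


def granger_classify(
    a,
    b,
    lag: float,
    alpha: float = 0.05,
    rate: float | None = None,
    bout_id: str | None = None,
) -> GrangerResult:
    """Directional Granger tests at a given lag (seconds) plus classification.

    A bout too short for the requested lag is tested at the largest feasible
    order and flagged; a degenerate (constant) series yields classification
    ``none`` with a flag.
    """
    av, ra = _values(a)
    bv, _ = _values(b)
    rate = ra if rate is None else rate
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = max(1, int(round(lag * rate)))
    flags: list[str] = []
    while p > 1 and av.size - p <= 2 * (1 + 2 * p) + 1:
        p -= 1
    if p != max(1, int(round(lag * rate))):
        flags.append("lag_truncated")
    nan_result = GrangerResult(
        bout_id, math.nan, math.nan, math.nan, math.nan, p / rate,
        CLASS_NONE, n_samples=av.size, flags=flags,
    )
    if av.size - p <= 2 * (1 + 2 * p) + 1:
        nan_result.flags.append("too_short")
        return nan_result
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        nan_result.flags.append("degenerate")
        return nan_result
    f_f2h, p_f2h, _ = granger_f(av, bv, p, "f2h")
    f_h2f, p_h2f, _ = granger_f(av, bv, p, "h2f")
    if math.isnan(p_f2h) or math.isnan(p_h2f):
        nan_result.flags.append("degenerate")
        return nan_result
    front = p_f2h < alpha
    hind = p_h2f < alpha
    if front and hind:
        cls = CLASS_BOTH
    elif front:
        cls = CLASS_FRONT
    elif hind:
        cls = CLASS_HIND
    else:
        cls = CLASS_NONE
    return GrangerResult(
        bout_id, p_f2h, p_h2f, f_f2h, f_h2f, p / rate, cls,
        n_samples=av.size, flags=flags,
    )
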