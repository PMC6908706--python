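"""Circular statistics for step phases on a reference period.

Each step onset is expressed as an angle on a circle whose full turn equals
one reference period T (360 degrees = T seconds; a subject's first step in a
bout anchors 0 degrees).  A phase-locked walker concentrates near 0; the mean
resultant length R-bar measures that concentration (1 = perfect lock, 0 =
uniform).  The module implements:

* circular summary (mean angle, R-bar, circular SD, Rayleigh uniformity test),
* the Watson-Williams high-concentration F test (circular one-way ANOVA),
* the Jammalamadaka-Sarma circular-circular correlation with an asymptotic
  p-value and a seeded percentile-bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class PhaseAngles:
    """Step onsets as angles (degrees, [0, 360)) on a reference period."""

    angles: np.ndarray
    reference_period: float
    anchor: float
    subject: str | None = None
    bout_id: str | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.reference_period <= 0:
            raise ValueError("reference period must be > 0")
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() >= 360):
            raise ValueError("angles must lie in [0, 360)")

    def __len__(self) -> int:
        return self.angles.size

    @property
    def radians(self) -> np.ndarray:
        return np.deg2rad(self.angles)


@dataclass
class CircularSummary:
    mean_angle: float      # degrees in [0, 360)
    circ_sd: float         # degrees, sqrt(-2 ln R_bar) convention
    r_bar: float           # mean resultant length in [0, 1]
    rayleigh_p: float
    n: int


@dataclass
class CircANOVAResult:
    F: float
    df_between: int
    df_within: int
    p: float
    kappa_hat: float
    low_concentration_warning: bool = False


@dataclass
class CircCorrResult:
    r_js: float
    p: float
    ci95: tuple[float, float]
    n: int
    n_boot: int
    seed: int | None = None


def to_phase_angles(
    onsets,
    period: float,
    t0: float | None = None,
    *,
    subject: str | None = None,
    bout_id: str | None = None,
) -> PhaseAngles:
    """Map onsets to angles: angle_i = 360 * (((t_i - t0) mod T) / T).

    ``t0`` defaults to the first onset, which therefore maps exactly to 0.
    Adding any integer multiple of T to all onsets leaves the angles
    unchanged.
    """
    onsets = np.asarray(onsets, dtype=float)
    if period <= 0:
        raise ValueError("period must be > 0")
    if onsets.size == 0:
        raise ValueError("need at least one onset")
    if t0 is None:
        t0 = float(onsets[0])
    angles = 360.0 * (np.mod(onsets - t0, period) / period)
    angles = np.where(angles >= 360.0, angles - 360.0, angles)  # guard fp edge
    return PhaseAngles(angles, period, t0, subject=subject, bout_id=bout_id)


def _resultant(rad: np.ndarray) -> tuple[float, float]:
    """(mean resultant length R_bar, mean direction in radians)."""
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def rayleigh_p(n: int, r_bar: float) -> float:
    """Rayleigh uniformity test, standard large-sample approximation."""
    R = n * r_bar
    z = math.sqrt(1 + 4 * n + 4 * (n * n - R * R)) - (1 + 2 * n)
    return float(min(1.0, max(math.exp(z), np.nextafter(0, 1))))


def circular_summary(angles: PhaseAngles | np.ndarray) -> CircularSummary:
    """Mean direction, mean resultant length, circular SD and Rayleigh p."""
    rad = angles.radians if isinstance(angles, PhaseAngles) else np.deg2rad(np.asarray(angles, float))
    n = rad.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    r_bar, mean_rad = _resultant(rad)
    mean_deg = math.degrees(mean_rad) % 360.0
    if r_bar >= 1.0:
        circ_sd = 0.0
    elif r_bar <= 0.0:
        circ_sd = math.inf
    else:
        circ_sd = math.degrees(math.sqrt(-2.0 * math.log(r_bar)))
    return CircularSummary(mean_deg, circ_sd, r_bar, rayleigh_p(n, r_bar), n)


def kappa_fisher(r_bar: float) -> float:
    """Fisher's approximation to the von Mises concentration parameter."""
    if r_bar < 0.53:
        return 2 * r_bar + r_bar**3 + 5 * r_bar**5 / 6
    if r_bar < 0.85:
        return -0.4 + 1.39 * r_bar + 0.43 / (1 - r_bar)
    denom = r_bar**3 - 4 * r_bar**2 + 3 * r_bar
    return 1.0 / denom if denom > 0 else math.inf


def circular_anova(groups) -> CircANOVAResult:
    """Watson-Williams test for equal mean directions across groups.

    High-concentration F test with the (1 + 3/(8*kappa)) correction, kappa
    estimated by Fisher's approximation from the mean within-group resultant
    length.  Groups whose concentration is too low for the approximation
    (R_bar < 0.45) set ``low_concentration_warning`` rather than failing.
    """
    rads = [
        g.radians if isinstance(g, PhaseAngles) else np.deg2rad(np.asarray(g, float))
        for g in groups
    ]
    k = len(rads)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(r.size < 2 for r in rads):
        raise ValueError("each group needs at least 2 angles")
    ns = np.array([r.size for r in rads])
    N = int(ns.sum())
    # per-group resultant vector lengths (unnormalized)
    Ri = np.array([n * _resultant(r)[0] for n, r in zip(ns, rads)])
    pooled = np.concatenate(rads)
    R = N * _resultant(pooled)[0]
    rw = float(Ri.sum() / N)
    kappa = kappa_fisher(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    df_b, df_w = k - 1, N - k
    denom = N - Ri.sum()
    if denom <= 0:  # all groups perfectly concentrated
        F = 0.0 if Ri.sum() - R <= 1e-12 else math.inf
    else:
        F = correction * (df_w * (Ri.sum() - R)) / (df_b * denom)
    F = max(float(F), 0.0)
    p = float(stats.f.sf(F, df_b, df_w)) if math.isfinite(F) else 0.0
    warn = bool(any(Ri / ns < 0.45))
    return CircANOVAResult(F, df_b, df_w, p, kappa, warn)


def _r_js(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Jammalamadaka-Sarma circular correlation coefficient (radians in)."""
    a = np.sin(alpha - _resultant(alpha)[1])
    b = np.sin(beta - _resultant(beta)[1])
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def circular_correlation(
    a: PhaseAngles | np.ndarray,
    b: PhaseAngles | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 20191212,
) -> CircCorrResult:
    """Jammalamadaka-Sarma correlation of two paired circular samples.

    Samples are paired by index and truncated to the common length (>= 3).
    The p-value uses the standard asymptotic normal approximation; the 95% CI
    is a percentile bootstrap over paired resamples with a fixed seed.
    """
    ra = a.radians if isinstance(a, PhaseAngles) else np.deg2rad(np.asarray(a, float))
    rb = b.radians if isinstance(b, PhaseAngles) else np.deg2rad(np.asarray(b, float))
    n = min(ra.size, rb.size)
    if n < 3:
        raise ValueError("need at least 3 paired angles")
    ra, rb = ra[:n], rb[:n]
    r = _r_js(ra, rb)

    sa = np.sin(ra - _resultant(ra)[1])
    sb = np.sin(rb - _resultant(rb)[1])
    l20 = float(np.mean(sa**2))
    l02 = float(np.mean(sb**2))
    l22 = float(np.mean(sa**2 * sb**2))
    if l22 > 0 and l20 > 0 and l02 > 0:
        z = math.sqrt(n * l20 * l02 / l22) * r
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = math.nan

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = _r_js(ra[idx], rb[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CircCorrResult(r, p, (float(lo), float(hi)), n, n_boot, seed)


def permutation_anova_p(
    groups,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Permutation reference for the Watson-Williams test.

    The statistic is the between-group spread of resultant vectors
    (sum_i R_i - R); group labels are permuted.  Used as an independent check
    of the parametric F approximation on small samples.
    """
    rads = [
        g.radians if isinstance(g, PhaseAngles) else np.deg2rad(np.asarray(g, float))
        for g in groups
    ]
    ns = [r.size for r in rads]
    pooled = np.concatenate(rads)
    N = pooled.size

    def statistic(sample: np.ndarray) -> float:
        tot, start = 0.0, 0
        for n in ns:
            tot += n * _resultant(sample[start : start + n])[0]
            start += n
        return tot - N * _resultant(sample)[0]

    obs = statistic(pooled)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(pooled)) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
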