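"""Synthetic coupled-walker generator (linear phase-correction model).

Two walkers emit footfall onsets.  Within a bout both share a bout tempo
T_b (base period plus slow between-bout drift); each next onset is the
previous one plus T_b, plus per-step motor noise, minus a phase-correction
term proportional to the current asynchrony with the partner:

    t_{k+1} = t_k + T_b + N(0, motor_noise_sd) - gain * (t_k - s_k)

where s_k is the partner's onset nearest to t_k.  With symmetric gains
g_f, g_h the asynchrony contracts geometrically by the factor
(1 - g_f - g_h) per step, which is the standard first-order model of
sensorimotor synchronization.  Setting one gain to zero makes the other
walker the follower (directional coupling); both zero gives independent
metronomes (the null model for calibration studies).

Defaults emulate the observed behaviour: base tempo 0.89 s, per-bout mean
tempi spanning roughly 0.81-1.49 s, realized step-duration SD near 0.15 s,
bout durations 2.6-48 s, subjects starting slightly out of phase and locking
within the first steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .event_io import Bout, Dataset

_PERIOD_BOUNDS = (0.5, 1.6)   # plausible bipedal step periods, s
_MIN_STEP = 1e-3              # onsets must stay strictly increasing


@dataclass(frozen=True)
class WalkerParams:
    """Generative parameters of the coupled dyad.

    base_period
        Shared mean step period, seconds.
    motor_noise_sd
        SD of per-step timing noise, seconds.
    drift_sd
        SD of the between-bout tempo drift, seconds (bout tempo is
        base_period + N(0, drift_sd), truncated to 0.5-1.6 s).
    coupling_front_from_hind / coupling_hind_from_front
        Phase-correction gains in [0, 1]: how strongly each walker corrects
        toward the partner.
    initial_offset
        Hind walker's first-onset delay relative to the front walker, s.
    follow_offset
        Preferred asynchrony of the hind walker behind the front one, s.
        At 0 (default) the correction drives the asynchrony itself to zero
        (in-phase locking).  A positive value models reactive following: the
        follower's footfalls settle a fixed fraction of a second behind the
        leader's, which is what makes the leader temporally identifiable.
    """

    base_period: float = 0.89
    motor_noise_sd: float = 0.03
    drift_sd: float = 0.15
    coupling_front_from_hind: float = 0.25
    coupling_hind_from_front: float = 0.25
    initial_offset: float = 0.2
    follow_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.base_period <= 0:
            raise ValueError("base_period must be > 0")
        if self.motor_noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for g in (self.coupling_front_from_hind, self.coupling_hind_from_front):
            if not 0 <= g <= 1:
                raise ValueError("coupling gains must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_bouts: int = 28
    bout_duration_range: tuple[float, float] = (2.6, 48.0)
    rate: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")
        lo, hi = self.bout_duration_range
        if not 0 < lo <= hi:
            raise ValueError("bout duration range must be positive and ordered")


def _truncated_period(rng: np.random.Generator, mean: float, sd: float) -> float:
    lo, hi = _PERIOD_BOUNDS
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        t = rng.normal(mean, sd)
        if lo <= t <= hi:
            return float(t)
    return float(min(max(mean, lo), hi))


def _nearest(onsets: list[float], t: float) -> float:
    arr = np.asarray(onsets)
    return float(arr[np.argmin(np.abs(arr - t))])


def _simulate_bout(
    rng: np.random.Generator,
    bout_id: str,
    duration: float,
    period_front: float,
    period_hind: float,
    params: WalkerParams,
    offset_hind: float,
) -> Bout:
    """Iterate the phase-correction map until the bout duration is reached.

    Both walkers advance simultaneously per step index; the correction uses
    the partner's nearest already-emitted onset, so pairing does not assume
    the walkers stay in unison.
    """
    g_f = params.coupling_front_from_hind
    g_h = params.coupling_hind_from_front
    sd = params.motor_noise_sd
    off = params.follow_offset
    front = [0.0]
    hind = [offset_hind]
    done_f = done_h = False
    while not (done_f and done_h):
        # simultaneous update: both walkers correct against the partner's
        # onsets as of the previous step index
        snap_f, snap_h = list(front), list(hind)
        if not done_f:
            t_f = front[-1]
            # front walker prefers the partner `off` seconds behind itself
            err = t_f - _nearest(snap_h, t_f) + off
            nxt = t_f + period_front + rng.normal(0.0, sd) - g_f * err
            nxt = max(nxt, t_f + _MIN_STEP)
            if nxt <= duration:
                front.append(nxt)
            else:
                done_f = True
        if not done_h:
            t_h = hind[-1]
            err = t_h - _nearest(snap_f, t_h) - off
            nxt = t_h + period_hind + rng.normal(0.0, sd) - g_h * err
            nxt = max(nxt, t_h + _MIN_STEP)
            if nxt <= duration:
                hind.append(nxt)
            else:
                done_h = True
    return Bout(bout_id, np.asarray(front), np.asarray(hind))


def simulate_dyad(
    params: WalkerParams | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Generate a coupled-dyad Dataset, fully reproducible from the seed.

    Per bout, a shared tempo T_b is drawn (truncated normal around the base
    period), the hind walker starts ``initial_offset`` after the front one,
    and both walkers iterate the phase-correction update until the drawn
    bout duration (uniform over ``bout_duration_range``) is exhausted.
    """
    params = params or WalkerParams()
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_bouts)))
    bouts = []
    periods: list[float] = []
    for i in range(config.n_bouts):
        duration = rng.uniform(*config.bout_duration_range)
        t_b = _truncated_period(rng, params.base_period, params.drift_sd)
        periods.append(t_b)
        bouts.append(
            _simulate_bout(
                rng,
                f"bout{i + 1:0{width}d}",
                duration,
                t_b,
                t_b,
                params,
                params.initial_offset,
            )
        )
    return Dataset(
        bouts,
        provenance={
            "generator": "entrainkit.simulate.simulate_dyad",
            "seed": config.seed,
            "params": params,
            "bout_periods": periods,
        },
    )


def null_dataset(
    config: SimConfig | None = None,
    params: WalkerParams | None = None,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Fully uncoupled dyad: independent tempi and phases per walker.

    Both gains are forced to zero, each walker draws its own bout tempo, and
    the hind walker's initial offset is uniform over one period — the null
    model for type-I calibration of the synchrony and leadership tests.
    """
    params = params or WalkerParams()
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p0 = replace(params, coupling_front_from_hind=0.0, coupling_hind_from_front=0.0)
    width = max(2, len(str(config.n_bouts)))
    bouts = []
    for i in range(config.n_bouts):
        duration = rng.uniform(*config.bout_duration_range)
        t_f = _truncated_period(rng, p0.base_period, p0.drift_sd)
        t_h = _truncated_period(rng, p0.base_period, p0.drift_sd)
        offset = rng.uniform(0.0, min(t_f, t_h))
        bouts.append(
            _simulate_bout(rng, f"bout{i + 1:0{width}d}", duration, t_f, t_h, p0, offset)
        )
    return Dataset(
        bouts,
        provenance={
            "generator": "entrainkit.simulate.null_dataset",
            "seed": config.seed,
            "params": p0,
        },
    )
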