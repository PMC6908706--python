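"""End-to-end dyadic entrainment analysis.

``analyze`` runs the full per-bout and aggregate pipeline on an annotated
Dataset: pulse-series conversion and smoothing, per-bout tempo
(autocorrelation) and between-walker lag (cross-correlation), a pooled
autocorrelation that fixes the global reference period, circular statistics
of step phases on that period (per-subject summaries, Watson-Williams ANOVAs
by subject and by bout, Jammalamadaka-Sarma correlation), per-bout Granger
leadership classification at a globally AIC-selected lag, and one-sample
comparisons of the observed tempo against literature reference gaits.

Everything is deterministic given dataset + config (the bootstrap seed lives
in the config).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import causality, circular, timeseries
from .event_io import ROLE_FRONT, ROLE_HIND, Bout, Dataset

#: reference mean step periods (s) for solo bipedalism in Pan, used by the
#: one-sample tempo comparisons: wild-walking and captive-walking gaits.
DEFAULT_REFERENCE_TEMPOS: tuple[tuple[str, float], ...] = (
    ("wild", 0.81),
    ("captive", 1.21),
)


@dataclass(frozen=True)
class AnalysisConfig:
    rate_hz: float = 100.0
    filter_order: int = 3
    filter_cutoff_hz: float = 4.0
    ac_window_s: tuple[float, float] = (0.5, 1.5)
    xc_range_s: float = 0.5
    xc_increment_s: float = 1.0 / 24.0
    granger_max_lag_s: float = 0.3
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 20191212
    min_steps_per_subject: int = 2
    reference_tempos: tuple[tuple[str, float], ...] = DEFAULT_REFERENCE_TEMPOS


@dataclass
class TempoComparison:
    """One-sample t test of step durations against a reference tempo.

    Positive t means the sample is slower (longer step duration) than the
    reference.
    """

    label: str
    reference_mean: float
    t: float
    df: int
    p: float
    direction: str  # "slower" | "faster" | "equal"


@dataclass
class BoutSummary:
    bout_id: str
    duration: float
    n_steps_front: int
    n_steps_hind: int
    mean_step_front: float
    mean_step_hind: float
    ac_period_front: float | None
    ac_period_hind: float | None
    xc_max_lag: float | None
    mean_angle_front: float | None
    mean_angle_hind: float | None
    r_bar_front: float | None
    r_bar_hind: float | None
    granger_class: str | None
    granger: causality.GrangerResult | None = None


@dataclass
class AggregateReport:
    n_bouts: int
    excluded_bouts: list[str]
    mean_bout_duration: float
    min_bout_duration: float
    max_bout_duration: float
    sd_bout_duration: float
    pooled_mean_tempo: float
    tempo_sd_front: float
    tempo_sd_hind: float
    pooled_ac_period: float | None
    median_ac_period: float | None
    sd_ac_period: float | None
    modal_xc_lag: float | None
    mean_xc_lag: float | None
    sd_xc_lag: float | None
    rayleigh_front: circular.CircularSummary | None
    rayleigh_hind: circular.CircularSummary | None
    circ_anova_subject: circular.CircANOVAResult | None
    circ_anova_bout: circular.CircANOVAResult | None
    r_js: circular.CircCorrResult | None
    granger_lag_s: float | None
    granger_counts: dict[str, int]
    tempo_vs_reference: list[TempoComparison]
    config: AnalysisConfig | None = None


def compare_tempo(step_durations, reference_mean: float, label: str = "") -> TempoComparison:
    """One-sample t test of step durations against a reference constant."""
    d = np.asarray(step_durations, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 step durations")
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    if np.ptp(d) == 0:
        if float(d[0]) == reference_mean:
            return TempoComparison(label, reference_mean, 0.0, d.size - 1, 1.0, "equal")
        raise ValueError("zero-variance sample; t test undefined")
    res = stats.ttest_1samp(d, reference_mean)
    t = float(res.statistic)
    direction = "slower" if t > 0 else ("faster" if t < 0 else "equal")
    return TempoComparison(label, reference_mean, t, d.size - 1, float(res.pvalue), direction)


def _prepare_bout(bout: Bout, cfg: AnalysisConfig):
    """Per-subject (raw, smoothed) pulse series over the bout's common span.

    The smoothed series feed the correlation analyses; the Granger tests run
    on the raw impulse series, whose regression errors are serially
    independent under the no-coupling null (filtering induces an error
    autocorrelation that inflates the F test).
    """
    both = np.concatenate([bout.events_front, bout.events_hind])
    span = (float(both.min()), float(both.max()))
    out = {}
    for role, onsets in ((ROLE_FRONT, bout.events_front), (ROLE_HIND, bout.events_hind)):
        raw = timeseries.events_to_series(onsets, rate=cfg.rate_hz, span=span)
        sm = timeseries.smooth(raw, order=cfg.filter_order, cutoff=cfg.filter_cutoff_hz)
        out[role] = (raw, sm)
    return out


def _mode_lag(lags: list[float]) -> float:
    """Most frequent lag value (grid values repeat exactly); ties toward 0."""
    vals, counts = np.unique(np.asarray(lags), return_counts=True)
    best = counts.max()
    cands = vals[counts == best]
    return float(cands[np.argmin(np.abs(cands))])


def analyze(
    dataset: Dataset,
    config: AnalysisConfig | None = None,
) -> tuple[list[BoutSummary], AggregateReport]:
    """Run the full pipeline; returns per-bout summaries and the aggregate."""
    cfg = config or AnalysisConfig()
    if len(dataset) == 0:
        raise ValueError("dataset has no bouts")

    kept: list[Bout] = []
    excluded: list[str] = []
    for bout in dataset:
        if (
            bout.events_front.size >= cfg.min_steps_per_subject
            and bout.events_hind.size >= cfg.min_steps_per_subject
        ):
            kept.append(bout)
        else:
            excluded.append(bout.bout_id)
    if not kept:
        raise ValueError("no bout passes the minimum-step check")
    # canonical processing order: every aggregate is then exactly invariant
    # to the input bout order
    kept.sort(key=lambda b: b.bout_id)

    series = {b.bout_id: _prepare_bout(b, cfg) for b in kept}

    # ---- per-bout tempo and lag -------------------------------------------
    ac_lo, ac_hi = cfg.ac_window_s
    per_bout_ac: dict[str, dict[str, float]] = {}
    per_bout_xc: dict[str, float] = {}
    pooled_profiles: list[np.ndarray] = []
    n_pool = int(round(ac_hi * cfg.rate_hz)) + 1
    for b in kept:
        per_bout_ac[b.bout_id] = {}
        for role in (ROLE_FRONT, ROLE_HIND):
            s = series[b.bout_id][role][1]
            if s.duration > ac_hi:
                period, profile = timeseries.autocorrelation_period(s, window=(ac_lo, ac_hi))
                per_bout_ac[b.bout_id][role] = period
                full = timeseries.autocorrelation(s, max_lag=ac_hi)
                if full.values.size >= n_pool:
                    pooled_profiles.append(full.values[:n_pool])
        sf, sh = series[b.bout_id][ROLE_FRONT][1], series[b.bout_id][ROLE_HIND][1]
        if sf.duration > cfg.xc_range_s:
            lag, _ = timeseries.cross_correlation_lag(
                sf, sh, max_lag=cfg.xc_range_s, increment=cfg.xc_increment_s
            )
            per_bout_xc[b.bout_id] = lag

    # ---- global reference period from the pooled autocorrelation ----------
    pooled_ac_period = None
    if pooled_profiles:
        mean_profile = np.mean(np.vstack(pooled_profiles), axis=0)
        lags = np.arange(n_pool) / cfg.rate_hz
        keep = (lags >= ac_lo) & (lags <= ac_hi)
        pooled_ac_period = float(lags[keep][np.argmax(mean_profile[keep])])
    ac_values = [v for d in per_bout_ac.values() for v in d.values()]
    # fall back to mean inter-step interval when no bout spans the window
    global_T = pooled_ac_period
    if global_T is None:
        steps = np.concatenate(
            [np.diff(b.onsets(r)) for b in kept for r in (ROLE_FRONT, ROLE_HIND)]
        )
        global_T = float(np.mean(steps))

    # ---- circular statistics on the global period --------------------------
    angles: dict[str, dict[str, circular.PhaseAngles]] = {}
    for b in kept:
        angles[b.bout_id] = {}
        for role in (ROLE_FRONT, ROLE_HIND):
            angles[b.bout_id][role] = circular.to_phase_angles(
                b.onsets(role), global_T, subject=role, bout_id=b.bout_id
            )
    pooled_front = np.concatenate([angles[b.bout_id][ROLE_FRONT].angles for b in kept])
    pooled_hind = np.concatenate([angles[b.bout_id][ROLE_HIND].angles for b in kept])

    summary_front = circular.circular_summary(pooled_front) if pooled_front.size >= 2 else None
    summary_hind = circular.circular_summary(pooled_hind) if pooled_hind.size >= 2 else None
    anova_subject = None
    if pooled_front.size >= 2 and pooled_hind.size >= 2:
        anova_subject = circular.circular_anova([pooled_front, pooled_hind])
    bout_groups = [
        np.concatenate([angles[b.bout_id][ROLE_FRONT].angles, angles[b.bout_id][ROLE_HIND].angles])
        for b in kept
    ]
    anova_bout = None
    if len(bout_groups) >= 2 and all(g.size >= 2 for g in bout_groups):
        anova_bout = circular.circular_anova(bout_groups)
    paired_f, paired_h = [], []
    for b in kept:
        n = min(b.events_front.size, b.events_hind.size)
        paired_f.append(angles[b.bout_id][ROLE_FRONT].angles[:n])
        paired_h.append(angles[b.bout_id][ROLE_HIND].angles[:n])
    paired_f = np.concatenate(paired_f)
    paired_h = np.concatenate(paired_h)
    # canonical pair order so the bootstrap CI is invariant to bout order
    order = np.lexsort((paired_h, paired_f))
    paired_f, paired_h = paired_f[order], paired_h[order]
    r_js = None
    if paired_f.size >= 3:
        r_js = circular.circular_correlation(
            paired_f, paired_h, n_boot=cfg.n_boot, seed=cfg.seed
        )

    # ---- Granger leadership at the globally AIC-selected lag ---------------
    pairs = [
        (series[b.bout_id][ROLE_FRONT][0], series[b.bout_id][ROLE_HIND][0]) for b in kept
    ]
    granger_lag = None
    granger_results: dict[str, causality.GrangerResult] = {}
    counts = {k: 0 for k in (
        causality.CLASS_FRONT, causality.CLASS_HIND, causality.CLASS_BOTH, causality.CLASS_NONE,
    )}
    try:
        sel = causality.select_lag_global(pairs, max_lag=cfg.granger_max_lag_s, rate=cfg.rate_hz)
        granger_lag = sel.optimal_lag
    except ValueError:
        granger_lag = None
    if granger_lag is not None:
        for b in kept:
            rf, rh = series[b.bout_id][ROLE_FRONT][0], series[b.bout_id][ROLE_HIND][0]
            res = causality.granger_classify(
                rf, rh, granger_lag, alpha=cfg.alpha, bout_id=b.bout_id
            )
            granger_results[b.bout_id] = res
            counts[res.classification] += 1

    # ---- per-bout summaries ------------------------------------------------
    summaries: list[BoutSummary] = []
    for b in kept:
        af, ah = angles[b.bout_id][ROLE_FRONT], angles[b.bout_id][ROLE_HIND]
        sf = circular.circular_summary(af) if len(af) >= 2 else None
        sh = circular.circular_summary(ah) if len(ah) >= 2 else None
        g = granger_results.get(b.bout_id)
        summaries.append(
            BoutSummary(
                bout_id=b.bout_id,
                duration=b.duration,
                n_steps_front=int(b.events_front.size),
                n_steps_hind=int(b.events_hind.size),
                mean_step_front=float(np.mean(np.diff(b.events_front))),
                mean_step_hind=float(np.mean(np.diff(b.events_hind))),
                ac_period_front=per_bout_ac[b.bout_id].get(ROLE_FRONT),
                ac_period_hind=per_bout_ac[b.bout_id].get(ROLE_HIND),
                xc_max_lag=per_bout_xc.get(b.bout_id),
                mean_angle_front=sf.mean_angle if sf else None,
                mean_angle_hind=sh.mean_angle if sh else None,
                r_bar_front=sf.r_bar if sf else None,
                r_bar_hind=sh.r_bar if sh else None,
                granger_class=g.classification if g else None,
                granger=g,
            )
        )

    # ---- aggregate ---------------------------------------------------------
    durations = np.array([b.duration for b in kept])
    steps_front = np.concatenate([np.diff(b.events_front) for b in kept])
    steps_hind = np.concatenate([np.diff(b.events_hind) for b in kept])
    steps_all = np.concatenate([steps_front, steps_hind])
    xc_lags = list(per_bout_xc.values())
    comparisons = [
        compare_tempo(steps_all, ref, label) for label, ref in cfg.reference_tempos
    ] if steps_all.size >= 2 and np.ptp(steps_all) > 0 else []

    aggregate = AggregateReport(
        n_bouts=len(kept),
        excluded_bouts=sorted(excluded),
        mean_bout_duration=float(durations.mean()),
        min_bout_duration=float(durations.min()),
        max_bout_duration=float(durations.max()),
        sd_bout_duration=float(durations.std(ddof=1)) if durations.size > 1 else 0.0,
        pooled_mean_tempo=float(steps_all.mean()),
        tempo_sd_front=float(steps_front.std(ddof=1)) if steps_front.size > 1 else 0.0,
        tempo_sd_hind=float(steps_hind.std(ddof=1)) if steps_hind.size > 1 else 0.0,
        pooled_ac_period=pooled_ac_period,
        median_ac_period=float(np.median(ac_values)) if ac_values else None,
        sd_ac_period=float(np.std(ac_values, ddof=1)) if len(ac_values) > 1 else None,
        modal_xc_lag=_mode_lag(xc_lags) if xc_lags else None,
        mean_xc_lag=float(np.mean(xc_lags)) if xc_lags else None,
        sd_xc_lag=float(np.std(xc_lags, ddof=1)) if len(xc_lags) > 1 else None,
        rayleigh_front=summary_front,
        rayleigh_hind=summary_hind,
        circ_anova_subject=anova_subject,
        circ_anova_bout=anova_bout,
        r_js=r_js,
        granger_lag_s=granger_lag,
        granger_counts=counts,
        tempo_vs_reference=comparisons,
        config=cfg,
    )
    return summaries, aggregate


# ---------------------------------------------------------------------------
# report rendering


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def render_json(aggregate: AggregateReport, summaries: list[BoutSummary] | None = None) -> str:
    """Machine-readable report; parses back to the same structure."""
    payload = {"aggregate": _to_jsonable(aggregate)}
    if summaries is not None:
        payload["bouts"] = [_to_jsonable(s) for s in summaries]
    return json.dumps(payload, indent=2, sort_keys=True)


def _fmt(x, digits=3, unit=""):
    if x is None:
        return "n/a"
    return f"{x:.{digits}f}{unit}"


def render_markdown(aggregate: AggregateReport, summaries: list[BoutSummary] | None = None) -> str:
    """Human-readable summary mirroring the aggregate statistics."""
    a = aggregate
    lines = [
        "# Dyadic entrainment report",
        "",
        f"Bouts analysed: {a.n_bouts}"
        + (f" (excluded: {', '.join(a.excluded_bouts)})" if a.excluded_bouts else ""),
        f"Bout duration: mean {_fmt(a.mean_bout_duration, 2, ' s')}, "
        f"min {_fmt(a.min_bout_duration, 2, ' s')}, max {_fmt(a.max_bout_duration, 2, ' s')}, "
        f"SD {_fmt(a.sd_bout_duration, 2, ' s')}",
        "",
        "## Tempo",
        f"Pooled mean step duration: {_fmt(a.pooled_mean_tempo, 2, ' s')} "
        f"(SD front {_fmt(a.tempo_sd_front, 3, ' s')}, hind {_fmt(a.tempo_sd_hind, 3, ' s')})",
        f"Pooled autocorrelation maximum: {_fmt(a.pooled_ac_period, 2, ' s')} "
        f"(per-bout median {_fmt(a.median_ac_period, 2, ' s')}, SD {_fmt(a.sd_ac_period, 3, ' s')})",
        "",
        "## Synchrony",
        f"Cross-correlation max lag: mode {_fmt(a.modal_xc_lag, 4, ' s')}, "
        f"mean {_fmt(a.mean_xc_lag, 4, ' s')}, SD {_fmt(a.sd_xc_lag, 4, ' s')}",
    ]
    for role, s in (("front", a.rayleigh_front), ("hind", a.rayleigh_hind)):
        if s is not None:
            lines.append(
                f"{role}: mean angle {_fmt(s.mean_angle, 1)} deg, "
                f"R-bar {_fmt(s.r_bar, 2)}, Rayleigh p {_fmt(s.rayleigh_p, 4)}"
            )
    if a.circ_anova_subject is not None:
        s = a.circ_anova_subject
        lines.append(
            f"Circular ANOVA (subject): F({s.df_between},{s.df_within}) = "
            f"{_fmt(s.F, 3)}, p = {_fmt(s.p, 3)}"
        )
    if a.circ_anova_bout is not None:
        s = a.circ_anova_bout
        lines.append(
            f"Circular ANOVA (bout): F({s.df_between},{s.df_within}) = "
            f"{_fmt(s.F, 2)}, p = {_fmt(s.p, 4)}"
        )
    if a.r_js is not None:
        lines.append(
            f"Circular correlation r_JS = {_fmt(a.r_js.r_js, 3)} "
            f"(p = {_fmt(a.r_js.p, 4)}, CI95 {_fmt(a.r_js.ci95[0], 3)}-{_fmt(a.r_js.ci95[1], 3)})"
        )
    lines += [
        "",
        "## Leadership (Granger)",
        f"Optimal lag: {_fmt(a.granger_lag_s, 2, ' s')}",
        f"Counts: {a.granger_counts}",
    ]
    if a.tempo_vs_reference:
        lines += ["", "## Tempo vs reference gaits"]
        for c in a.tempo_vs_reference:
            lines.append(
                f"{c.label} ({c.reference_mean:.2f} s): t({c.df}) = {c.t:.2f}, "
                f"p = {c.p:.3g} ({c.direction})"
            )
    if a.config is not None:
        lines += ["", f"Config: {a.config}"]
    return "\n".join(lines) + "\n"
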