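# Methods

`entrainkit` quantifies rhythmic entrainment between two walkers (a "front"
and a "hind" subject) from annotated footfall onset times. This note records
the models, the numerical choices, and what the synthetic-data studies do and
do not establish.

## From onsets to series

Annotations are event times (seconds of foot–ground contact) grouped into
bouts. Each subject's onsets in a bout are converted to a pulse series at
`rate_hz` (default 100 Hz): a unit impulse at the sample nearest each onset,
zeros elsewhere. Two onsets rounding to one sample are rejected as physically
impossible. For the correlation analyses the series is smoothed with a
zero-phase (forward–backward) Butterworth low-pass, order 3, cutoff 4 Hz.
The cutoff is not dictated by the measurement chain; it was chosen as roughly
3.5× the stepping frequency (~1.1 Hz), low enough to suppress sampling
shimmer and high enough to pass the beat structure, and it is exposed in the
config. Edges use reflect padding of three times the filter order.

## Tempo and mutual lag

The stepping period is the lag of the maximum of the normalized (biased,
demeaned) autocorrelation inside a physiological window, default 0.5–1.5 s.
A train faster than the window's lower edge is reported at its first harmonic
inside the window — the window encodes the prior that bipedal step periods
live in this range. Ties break toward the smaller lag. The global reference
period is the argmax of the *average* autocorrelation profile over all
bout-subject series long enough to span the window (unweighted average; the
pooled peak is insensitive to reasonable weightings).

The between-subject lag is the argmax of the Pearson-normalized
cross-correlation of the two smoothed series, computed at native sample
resolution and then restricted to a 1/24 s grid (±0.5 s) by nearest native
lag; positive lag means the hind walker trails the front. Ties break toward
the smallest absolute lag, and an exact ±L tie toward the nonnegative lag
(conservative toward the synchrony null).

## Circular statistics

Step onsets are mapped to angles on the global reference period T:
`angle = 360 · (((t − t0) mod T) / T)`, with t0 the subject's first step in
the bout (so the first step is exactly 0°). Note this is a *cumulative*
phase: a bout whose tempo differs from T by ΔT advances 360·ΔT/T degrees per
step, so pooled concentration (R̄) on a single global T degrades quickly with
between-bout tempo drift. Passing per-bout concentration with drifting tempi
is therefore informative; pooled R̄ is reported as the protocol defines it.

* Summary: mean direction, mean resultant length R̄, circular SD
  `sqrt(−2 ln R̄)` (reported in degrees; one of several conventions), and the
  Rayleigh uniformity test with the standard large-sample p approximation
  `exp(sqrt(1+4n+4(n²−R²)) − (1+2n))`.
* Watson–Williams circular ANOVA: the high-concentration F test with the
  `1 + 3/(8κ̂)` correction, κ̂ from Fisher's approximation at the mean
  within-group resultant length. Groups with R̄ < 0.45 set a warning flag —
  the approximation is unreliable there — rather than failing; a
  permutation reference (`permutation_anova_p`, statistic ΣRᵢ − R) is
  provided and is what the tests compare against.
* Jammalamadaka–Sarma circular–circular correlation r_JS with the asymptotic
  normal p-value and a percentile bootstrap CI (default 1000 paired
  resamples, fixed seed). Front/hind steps are paired by ordinal index
  within bout, truncated to the common length; pairs are put in a canonical
  order before resampling so the CI does not depend on bout order.

## Leadership (Granger causality)

Each bout's pair of series is modelled as a bivariate VAR(p) fit by OLS, one
equation per series. The lag order grid is 1..30 samples (10 ms..0.3 s); all
candidates are estimated on a common sample (dropping max-order presample
rows) and scored by AIC = ln det Σ̂ + 2k/n; the single global order minimizes
the AIC averaged over bouts. Per direction, an F test of joint nullity of
the cross-lag coefficients (restricted vs full OLS, numerator df = p,
denominator df = n − 2p − 1) gives a p-value; a bout is classified
front-leads / hind-leads / bidirectional / none by comparing both p-values
to α = 0.05 (no multiple-testing correction across bouts; a correction can
be layered on the per-bout table). Bouts too short for the chosen order are
tested at the largest feasible order and flagged.

The Granger tests run on the **raw** impulse series, not the smoothed ones.
Zero-phase filtering is non-causal — it writes information about future
onsets into past samples, which is fatal for an inference whose whole content
is temporal precedence — and any filtering leaves serially dependent
regression errors that the F test's error model does not absorb. Measured on
2000 uncoupled bouts, the per-direction rejection at α = 0.05 is ≈ 0.05–0.07
on raw series versus 0.10–0.14 on filtered series (zero-phase or causal).
The residual mild anticonservativeness (~0.06 empirical) comes from the
binary, heteroscedastic response; it sits inside the ±0.02 calibration band
the package tests for.

## The coupled-walker generator

`simulate_dyad` implements the standard first-order linear phase-correction
model of sensorimotor synchronization, operating directly on event times:

    t_{k+1} = t_k + T_b + N(0, σ_motor) − g · (t_k − s_k − δ_pref)

where s_k is the partner's nearest already-emitted onset and δ_pref the
walker's preferred asynchrony (+`follow_offset` for the hind walker,
−`follow_offset` for the front; zero by default). Both walkers advance
simultaneously per step index, so with symmetric gains the asynchrony
contracts geometrically by (1 − g_f − g_h) per step. The per-bout tempo T_b
is base period + N(0, drift_sd) truncated to 0.5–1.6 s; bout durations are
uniform on 2.6–48 s.

Defaults (the study conditions): base period 0.89 s; motor noise SD 0.03 s
per step; drift SD 0.15 s per bout; symmetric gains 0.25/0.25 (mutual
pacing — realized step durations then have mean ≈ 0.89 s and SD ≈ 0.13–0.17 s
and per-bout mean tempi span ≈ 0.8–1.5 s); initial offset 0.2 s, which the
total gain of 0.5 halves each step so the dyad is in phase within the first
few steps; 28 bouts. `null_dataset` forces both gains to zero, draws each
walker's tempo independently, and randomizes the initial phase — the null
model for type-I calibration.

### Why directional recovery needs a follower offset

Under the pure zero-offset phase-correction map the asynchrony converges to
zero and the leader's innovations reach the follower only one full period
later (≈ 0.89 s) — outside the 0–0.3 s VAR grid. In that regime Granger
direction at sub-period lags reflects only which walker happens to fire
first, and a designated leader is not identifiable in principle. Reactive
following (`follow_offset` > 0: the follower's footfalls settle a fixed
fraction of a second behind the leader's) puts the leader's onset inside the
follower's regression window and nowhere else, and the designated leader is
then recovered in ≈ 95% of bouts. The directional-recovery study therefore
uses one-way gain 0.7, motor noise 0.02 s, follow offset 0.15 s; the mutual
(default) condition keeps offset 0 and is classified bidirectional in ≈ 90%
of bouts.

## What the synthetic studies show — and what they do not

The generator reproduces the statistical structure the analysis assumes:
point events on a drifting common tempo, phase coupling of adjustable
strength and direction, realistic bout lengths. It does not model gait
biomechanics, turning or obstacle negotiation, annotation error (add it via
`reliability` fixtures if needed), or missed/extra footfall codings. Passing
calibration and recovery on simulated dyads therefore validates the
estimators' operating characteristics under the assumed event-time model,
not the behavioural coding process itself.

## Problem sizes and numerics

The calibration study uses 2000 null bouts (global lag selected on a
50-bout subsample, then all bouts classified at that lag — the summed-AIC
curve is stable well below 50 bouts); recovery studies use 200 bouts; the
defaults study uses 28. OLS uses `numpy.linalg.lstsq` (SVD); constant series
raise a degeneracy error and degenerate bouts are flagged, not fatal.
Angles are kept in degrees at the API surface and converted to radians
internally. All randomness flows through `numpy.random.default_rng` seeded
from the config — same dataset + config + seed means byte-identical JSON
reports.

## Known limitations

* The Watson–Williams test assumes high, roughly equal concentrations; the
  warning flag is the only guard, and the permutation reference is the
  fallback for small or diffuse samples.
* The classical Granger F on binary impulse series is mildly
  anticonservative (~0.06 at nominal 0.05); a robust-covariance variant is
  deliberately out of scope because the textbook statistic is part of the
  protocol.
* Leadership classification reads temporal precedence; it cannot distinguish
  "A anticipates B" from "B reacts to A" — a limitation inherent to Granger
  causality on phase-locked rhythms, made explicit by the simulator.
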