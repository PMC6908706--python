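# entrainkit

Dyadic rhythmic-entrainment analysis of annotated step onsets: tempo
estimation, synchrony quantification via circular statistics, and pacemaker
(leadership) inference via Granger causality — plus a coupled-walker
simulator that makes every stage verifiable without video data.

The package is for behavioural researchers who have coded footfall onset
times for two subjects walking together (e.g. from video, one row per
foot–ground contact) and want to answer, per bout and in aggregate:

* **How fast do they step?** Onsets become 100 Hz pulse series; the stepping
  period is the autocorrelation maximum in a physiological window
  (0.5–1.5 s), pooled across bouts for a global reference period T.
* **Are they synchronized?** Cross-correlation lag between the two series on
  a 1/24 s grid (±0.5 s); step onsets as phase angles on T
  (angle = 360°·((t − t₀) mod T)/T) summarized by mean direction, mean
  resultant length R̄, Rayleigh uniformity test, Watson–Williams circular
  ANOVA across subjects and bouts, and the Jammalamadaka–Sarma circular
  correlation r_JS between paired front/hind steps with a bootstrap CI.
* **Who sets the pace?** Per bout, a bivariate VAR on the paired impulse
  series with AIC-selected lag order (grid 0.01–0.3 s); directional F tests
  of the cross-lag coefficients classify each bout as front-leads,
  hind-leads, bidirectional or none at α = 0.05.

The simulator (`entrainkit.simulate`) implements the linear phase-correction
model of sensorimotor synchronization on event times,
`t_{k+1} = t_k + T_b + noise − gain·(asynchrony − preferred offset)`, with
per-bout tempo drift, and drives calibration (uncoupled null) and
parameter-recovery studies. See `docs/methods.md` for the full model
descriptions and design rationale.

## Worked example

```python
import entrainkit as ek

# a synthetic 28-bout mutually coupled dyad (defaults: base tempo 0.89 s,
# symmetric coupling, per-bout tempo drift, bouts 2.6-48 s)
ds = ek.simulate_dyad(config=ek.SimConfig(n_bouts=28, seed=3))
summaries, agg = ek.analyze(ds)
print(f"tempo {agg.pooled_mean_tempo:.2f} s, "
      f"bout duration {agg.mean_bout_duration:.1f} s, "
      f"modal xc lag {agg.modal_xc_lag:.3f} s, "
      f"r_JS {agg.r_js.r_js:.2f}, granger {agg.granger_counts}")
```

prints

```
tempo 0.89 s, bout duration 24.4 s, modal xc lag 0.000 s, r_JS 0.88, granger {'front_leads': 7, 'hind_leads': 0, 'bidirectional': 21, 'none': 0}
```

The pooled step duration recovers the generative base tempo (0.89 s); the
modal cross-correlation lag of 0 s says the walkers are in step; the high
circular correlation says their step phases covary; and the mutual coupling
shows up as mostly bidirectional Granger classifications.

The same analysis runs on real annotation CSVs (columns `time`, `subject` ∈
{front, hind}, `bout`) from the command line:

```sh
entrainkit validate events.csv
entrainkit reliability coderA.csv coderB.csv --tolerance 0.5
entrainkit simulate --n-bouts 28 --seed 1 -o sim.csv
entrainkit analyze events.csv -o report/   # report.json, report.md, bouts.tsv, granger.tsv, angles.tsv
```

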