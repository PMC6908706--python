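"""Coupled-walker generator: determinism, closed-form dynamics, and the
statistical structure the analysis assumes."""

import numpy as np
import pytest
from scipy.stats import binomtest

import entrainkit as ek
from entrainkit import causality
from entrainkit.event_io import ROLE_FRONT, ROLE_HIND
from entrainkit.pipeline import AnalysisConfig, _prepare_bout


def relative_phase_r_bar(dataset):
    """Mean resultant length of hind-vs-front relative phase, pooled."""
    angles = []
    for b in dataset:
        if b.events_front.size < 2:
            continue
        T = float(np.mean(np.diff(b.events_front)))
        for t in b.events_hind:
            nearest = b.events_front[np.argmin(np.abs(b.events_front - t))]
            angles.append(2 * np.pi * (((t - nearest) % T) / T))
    angles = np.asarray(angles)
    return float(np.hypot(np.cos(angles).mean(), np.sin(angles).mean()))


def raw_pairs(dataset):
    cfg = AnalysisConfig()
    out = []
    for b in dataset:
        s = _prepare_bout(b, cfg)
        out.append((s[ROLE_FRONT][0], s[ROLE_HIND][0]))
    return out


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        c = ek.SimConfig(n_bouts=5, seed=9)
        assert ek.simulate_dyad(config=c) == ek.simulate_dyad(config=c)
        assert ek.null_dataset(c) == ek.null_dataset(c)

    def test_serialized_round_is_byte_identical(self, tmp_path):
        c = ek.SimConfig(n_bouts=4, seed=9)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ek.write_events(ek.simulate_dyad(config=c), p1)
        ek.write_events(ek.simulate_dyad(config=c), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDynamics:
    def test_uncoupled_noiseless_metronomes(self):
        params = ek.WalkerParams(
            motor_noise_sd=0.0, drift_sd=0.0,
            coupling_front_from_hind=0.0, coupling_hind_from_front=0.0,
            initial_offset=0.2,
        )
        ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=1, bout_duration_range=(20, 20), seed=0))
        b = ds.bouts[0]
        np.testing.assert_allclose(np.diff(b.events_front), 0.89, atol=1e-12)
        np.testing.assert_allclose(b.events_hind - b.events_front[: b.events_hind.size], 0.2, atol=1e-12)

    def test_symmetric_gain_halves_asynchrony(self):
        # total gain 0.5: the asynchrony map d -> (1 - g_f - g_h) d contracts
        # by exactly one half per step
        params = ek.WalkerParams(
            motor_noise_sd=0.0, drift_sd=0.0,
            coupling_front_from_hind=0.25, coupling_hind_from_front=0.25,
            initial_offset=0.2,
        )
        ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=1, bout_duration_range=(15, 15), seed=0))
        b = ds.bouts[0]
        n = min(b.events_front.size, b.events_hind.size)
        d = b.events_hind[:n] - b.events_front[:n]
        np.testing.assert_allclose(d, 0.2 * 0.5 ** np.arange(n), atol=1e-10)

    def test_full_gains_zero_noise_still_valid(self):
        params = ek.WalkerParams(
            motor_noise_sd=0.0, drift_sd=0.0,
            coupling_front_from_hind=1.0, coupling_hind_from_front=1.0,
            initial_offset=0.0,
        )
        ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=1, bout_duration_range=(10, 10), seed=0))
        b = ds.bouts[0]
        assert np.all(np.diff(b.events_front) > 0)
        assert np.all(np.diff(b.events_hind) > 0)
        np.testing.assert_allclose(b.events_hind[: b.events_front.size], b.events_front[: b.events_hind.size], atol=1e-10)

    def test_follow_offset_sustained(self):
        params = ek.WalkerParams(
            motor_noise_sd=0.0, drift_sd=0.0,
            coupling_front_from_hind=0.0, coupling_hind_from_front=0.7,
            initial_offset=0.2, follow_offset=0.15,
        )
        ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=1, bout_duration_range=(30, 30), seed=0))
        b = ds.bouts[0]
        n = min(b.events_front.size, b.events_hind.size)
        d = b.events_hind[:n] - b.events_front[:n]
        np.testing.assert_allclose(d[12:], 0.15, atol=1e-6)


class TestStatisticalStructure:
    def test_realized_step_durations_in_band(self, default_dataset):
        steps = np.concatenate(
            [np.diff(b.events_front) for b in default_dataset]
            + [np.diff(b.events_hind) for b in default_dataset]
        )
        assert 0.8 <= steps.mean() <= 1.0
        assert 0.1 <= steps.std(ddof=1) <= 0.2

    def test_bout_tempi_stay_inside_observed_band(self, default_dataset):
        for b in default_dataset:
            assert 0.5 <= np.mean(np.diff(b.events_front)) <= 1.65

    def test_synchrony_monotone_in_symmetric_gain(self):
        r_bars, ses = [], []
        for i, gain in enumerate((0.0, 0.1, 0.2, 0.3, 0.4, 0.5)):
            params = ek.WalkerParams(
                coupling_front_from_hind=gain / 2, coupling_hind_from_front=gain / 2
            )
            per_bout = []
            ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=200, seed=50 + i))
            for b in ds:
                per_bout.append(relative_phase_r_bar(ek.Dataset([b])))
            r_bars.append(np.mean(per_bout))
            ses.append(np.std(per_bout, ddof=1) / np.sqrt(len(per_bout)))
        for k in range(1, len(r_bars)):
            assert r_bars[k] >= r_bars[k - 1] - (ses[k] + ses[k - 1])

    def test_null_relative_phase_near_uniform(self):
        ds = ek.null_dataset(ek.SimConfig(n_bouts=200, seed=77))
        assert relative_phase_r_bar(ds) < 0.15

    def test_directional_coupling_biases_leadership(self):
        params = ek.WalkerParams(
            coupling_front_from_hind=0.0, coupling_hind_from_front=0.5
        )
        ds = ek.simulate_dyad(params, ek.SimConfig(n_bouts=500, seed=88))
        pairs = raw_pairs(ds)
        sel = causality.select_lag_global(pairs[:50], max_lag=0.3)
        front = hind = 0
        for a, b in pairs:
            cls = causality.granger_classify(a, b, sel.optimal_lag).classification
            front += cls == causality.CLASS_FRONT
            hind += cls == causality.CLASS_HIND
        assert front > hind
        assert binomtest(front, front + hind, 0.5, alternative="greater").pvalue < 0.01
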