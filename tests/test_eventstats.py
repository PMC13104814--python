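"""Swim-matched trials, triggered averages, stress, lag and gain fits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.isotonic import IsotonicRegression

from oxyallo.eventstats import (
    LaggedLowess,
    MatchingError,
    fit_gain_model,
    fit_lag_lowess,
    hypoxic_stress,
    select_matched_trials,
    spike_vigor_regression,
    swim_po2_metrics,
    swim_series,
    triggered_average,
)
from oxyallo.paradigm import Epoch, Paradigm
from oxyallo.synthdata import O2System, rasterize_vigor, simulate_po2


def bout_table(onsets, vigors, dur=0.2):
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {"onset_s": onsets, "offset_s": onsets + dur,
         "vigor": np.asarray(vigors, dtype=float)}
    )


WINDOWS = {"normoxia": (0.0, 100.0), "hypoxia": (100.0, 200.0)}


class TestMatchedTrials:
    def test_identical_statistics_all_matched(self):
        on_n = np.arange(5.0, 95.0, 5.0)
        on_h = on_n + 100.0
        bouts = bout_table(np.concatenate([on_n, on_h]),
                           np.ones(2 * on_n.size))
        norm, hyp = select_matched_trials(bouts, windows=WINDOWS,
                                          duration=200.0)
        assert len(norm) == len(hyp) == on_n.size

    def test_disjoint_vigor_raises(self):
        on_n = np.arange(5.0, 95.0, 5.0)
        on_h = on_n + 100.0
        bouts = bout_table(np.concatenate([on_n, on_h]),
                           np.concatenate([np.ones(on_n.size),
                                           2.0 * np.ones(on_h.size)]))
        with pytest.raises(MatchingError, match="tolerance"):
            select_matched_trials(bouts, windows=WINDOWS, duration=200.0)

    def test_too_few_candidates_raises(self):
        bouts = bout_table([5.0, 105.0], [1.0, 1.0])
        with pytest.raises(MatchingError, match="candidate count"):
            select_matched_trials(bouts, windows=WINDOWS, duration=200.0)

    def test_planted_subset_matches_exhaustive_pairing(self):
        # half the hypoxia trials have a vigor twin in normoxia, half do not
        rng = np.random.default_rng(0)
        v_norm = np.linspace(1.0, 2.0, 12)
        v_hyp = np.concatenate([v_norm[:6], np.full(6, 10.0)])
        on_n = np.arange(5.0, 95.0, 7.0)[:12]
        on_h = np.arange(105.0, 195.0, 7.0)[:12]
        bouts = bout_table(np.concatenate([on_n, on_h]),
                           np.concatenate([v_norm, v_hyp]))
        norm, hyp = select_matched_trials(bouts, windows=WINDOWS,
                                          duration=200.0, min_trials=6)
        assert sorted(t.vigor for t in hyp) == sorted(v_norm[:6])
        # brute force: every matchable hypoxia trial is matched
        matchable = {
            i for i, vh in enumerate(v_hyp)
            if any(abs(vh - vn) / vn <= 0.2 for vn in v_norm)
        }
        assert len(hyp) == len(matchable)

    def test_short_isi_trials_excluded(self):
        onsets = np.array([10.0, 10.5, 20.0])  # second bout 0.3 s after first
        bouts = bout_table(onsets, np.ones(3))
        from oxyallo.eventstats import _candidate_trials

        trials = _candidate_trials(bouts, (0.0, 100.0), "normoxia", 1.0, 100.0)
        assert [t.onset_s for t in trials] == [10.0, 20.0]

    def test_swim_series_grouping(self):
        bouts = bout_table([1.0, 2.0, 10.0], [1.0, 2.0, 3.0])
        series = swim_series(bouts, min_pause=5.0)
        assert len(series) == 2
        assert series.loc[0, "vigor"] == 3.0


class TestTriggeredAverage:
    def test_identical_trials_zero_sem(self):
        fs = 10.0
        sig = np.zeros(int(100 * fs))
        snippet = np.sin(np.linspace(0, np.pi, int(5 * fs)))
        for onset in (20.0, 40.0, 60.0):
            i = int(onset * fs)
            sig[i : i + snippet.size] += snippet
        out = triggered_average(sig, fs, np.array([20.0, 40.0, 60.0]),
                                window=(-1.0, 5.0))
        assert np.allclose(out.sem, 0.0)
        assert np.allclose(out.mean[int(1.0 * fs):], snippet, atol=1e-12)

    def test_mirror_trials_cancel(self):
        fs = 10.0
        sig = np.zeros(int(100 * fs))
        bump = np.ones(int(2 * fs))
        sig[int(20 * fs) : int(22 * fs)] = bump
        sig[int(60 * fs) : int(62 * fs)] = -bump
        out = triggered_average(sig, fs, np.array([20.0, 60.0]),
                                window=(-1.0, 3.0))
        assert np.allclose(out.mean, 0.0)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        fs = 20.0
        sig = rng.standard_normal(int(300 * fs))
        onsets = np.array([50.0, 120.0, 200.0, 260.0])
        out = triggered_average(sig, fs, onsets, window=(-2.0, 10.0))
        i0, i1, nb = int(-2 * fs), int(10 * fs), int(fs)
        snips = []
        for onset in onsets:
            c = int(round(onset * fs))
            snips.append(sig[c + i0 : c + i1] - sig[c - nb : c].mean())
        arr = np.asarray(snips)
        assert np.allclose(out.mean, arr.mean(axis=0))
        assert np.allclose(out.sem, arr.std(axis=0, ddof=1) / 2.0)

    def test_out_of_range_trials_dropped_and_counted(self):
        fs = 10.0
        sig = np.zeros(int(50 * fs))
        out = triggered_average(sig, fs, np.array([2.0, 20.0, 49.0]),
                                window=(-1.0, 5.0))
        assert out.n == 1 + 1  # only the 20 s trial fully fits... plus none
        assert out.n + out.n_dropped == 3


class TestHypoxicStress:
    def test_constant_po2_zero_stress(self):
        po2 = np.full(1000, 6.0)
        out = hypoxic_stress(po2, fs=10.0, onset=50.0)
        assert np.allclose(out.stress, 0.0)

    def test_halving_gives_half(self):
        po2 = np.full(1000, 8.0)
        po2[600:] = 4.0
        out = hypoxic_stress(po2, fs=10.0, onset=50.0, window=(0.0, 30.0))
        assert out.stress[-1] == pytest.approx(0.5)

    def test_same_drop_doubles_at_half_baseline(self):
        drop = 1.0
        for base, expect in ((8.0, drop / 8.0), (4.0, drop / 4.0)):
            po2 = np.full(1000, base)
            po2[600:] -= drop
            out = hypoxic_stress(po2, fs=10.0, onset=50.0)
            assert out.stress[-1] == pytest.approx(expect)

    def test_unit_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        po2 = 6.0 + 0.5 * rng.standard_normal(1000).cumsum() * 0.01
        a = hypoxic_stress(po2, fs=10.0, onset=50.0)
        b = hypoxic_stress(po2 * 18.7, fs=10.0, onset=50.0)  # mg/L -> mmHg
        assert np.allclose(a.stress, b.stress)

    def test_nonpositive_baseline_rejected(self):
        po2 = np.zeros(1000)
        with pytest.raises(ValueError):
            hypoxic_stress(po2, fs=10.0, onset=50.0)


class TestSwimPo2Metrics:
    def test_triangle_dip_closed_form(self):
        fs = 10.0
        t = np.arange(0, 60.0, 1 / fs)
        po2 = np.full(t.size, 8.0)
        # linear fall of 2 mg/L over 4 s from t=20, linear recovery over 8 s
        fall = (t >= 20) & (t < 24)
        rise = (t >= 24) & (t < 32)
        po2[fall] -= (t[fall] - 20) / 4 * 2.0
        po2[rise] -= (1 - (t[rise] - 24) / 8) * 2.0
        m = swim_po2_metrics(po2, fs, onset=20.0, offset=20.5, window=30.0)
        assert not m.flagged
        assert m.minimum_drop == pytest.approx(-2.0, abs=0.05)
        assert m.decay_time_s == pytest.approx(2.0, abs=0.2)  # half of 4 s
        assert m.rise_time_s == pytest.approx(4.0, abs=0.2)  # half of 8 s
        assert m.stop_to_min_s == pytest.approx(4.0 - 0.5, abs=0.2)

    def test_flat_po2_flagged(self):
        m = swim_po2_metrics(np.full(600, 8.0), 10.0, onset=20.0, offset=20.2)
        assert m.flagged

    def test_deeper_consumption_deeper_minimum(self):
        sched = Paradigm(epochs=(Epoch("normoxia", 0, 120.0, 8.0),))
        bouts = bout_table([40.0], [2.0])
        drops = []
        for beta in (0.1, 0.2, 0.4):
            u = rasterize_vigor(bouts, 120.0, 0.1, smooth_s=2.0)
            po2, _ = simulate_po2(sched, u, O2System(beta=beta), dt=0.1)
            m = swim_po2_metrics(po2, 10.0, onset=40.0, offset=40.2)
            drops.append(m.minimum_drop)
        assert drops[0] > drops[1] > drops[2]  # more negative with beta


class TestLaggedLowess:
    @staticmethod
    def slow_signal(n, seed=0, fs=2.0):
        """Band-limited positive signal with decaying autocorrelation."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        from scipy.ndimage import gaussian_filter1d

        return gaussian_filter1d(x, 2.0 * fs)

    def test_planted_shift_recovered_exactly(self):
        fs = 2.0
        astro = self.slow_signal(1200, seed=1, fs=fs)
        k0 = 9  # 4.5 s
        stress = np.roll(astro, k0)
        fit = fit_lag_lowess(astro, stress, fs, tau_max=10.0)
        assert fit.tau == pytest.approx(k0 / fs)
        assert fit.r2 >= 0.999

    def test_independent_signals_negligible_r2(self):
        fs = 2.0
        astro = self.slow_signal(2000, seed=2, fs=fs)
        stress = self.slow_signal(2000, seed=3, fs=fs)
        fit = fit_lag_lowess(astro, stress, fs, tau_max=5.0)
        assert fit.r2 <= 0.05

    def test_exhaustive_small_grid_recovery(self):
        fs = 2.0
        astro = self.slow_signal(700, seed=4, fs=fs)
        for k0 in range(0, 11, 2):
            stress = np.roll(astro, k0)
            fit = fit_lag_lowess(astro, stress, fs, tau_max=5.0)
            assert fit.tau == pytest.approx(k0 / fs), k0

    def test_monotone_link_matches_isotonic_oracle(self):
        fs = 2.0
        rng = np.random.default_rng(5)
        astro = self.slow_signal(1500, seed=5, fs=fs)
        k0 = 6
        link = lambda x: np.tanh(1.5 * x) + 0.2 * x
        stress = link(np.roll(astro, k0)) + 0.05 * rng.standard_normal(1500)
        fit = fit_lag_lowess(astro, stress, fs, tau_max=6.0)
        assert fit.tau == pytest.approx(k0 / fs)
        x = astro[: astro.size - k0]
        y = stress[k0:]
        iso = IsotonicRegression(out_of_bounds="clip").fit(x, y)
        r2_iso = 1 - np.mean((y - iso.predict(x)) ** 2) / np.var(stress)
        assert abs(fit.r2 - r2_iso) <= 0.02

    def test_degenerate_predictor_flagged(self):
        fit = fit_lag_lowess(np.ones(100), np.random.default_rng(0)
                             .standard_normal(100), fs=2.0, tau_max=2.0)
        assert fit.degenerate and fit.r2 == 0.0

    def test_r2_curve_peaks_at_reported_lag(self):
        fs = 2.0
        astro = self.slow_signal(800, seed=6, fs=fs)
        stress = np.roll(astro, 4)
        fit = fit_lag_lowess(astro, stress, fs, tau_max=5.0)
        assert fit.tau_grid[int(np.argmax(fit.r2_curve))] == fit.tau


class TestGainModel:
    def test_exact_regressor_recovers_constant_gain(self):
        fr = 2.0
        bouts = bout_table(np.arange(10.0, 290.0, 10.0),
                           np.random.default_rng(0).uniform(0.5, 2, 28))
        from oxyallo.eventstats import _vigor_regressor

        reg, _ = _vigor_regressor(bouts, int(300 * fr), fr, 3.0)
        dff = 0.7 * reg
        po2 = np.full(3000, 6.0)
        fit = fit_gain_model(dff, fr, bouts, po2, po2_fs=10.0,
                             decay_grid=np.array([1.0, 3.0, 6.0]))
        assert fit.decay_s == pytest.approx(3.0)
        assert np.allclose(fit.blocks["gain"], 0.7, atol=1e-6)

    def test_planted_inverse_po2_gain_recovered(self, small_exp,
                                                short_schedule):
        # a flat-baseline astroglial population with the 1/pO2 swim gain,
        # driven by the shared experiment's behavior and oxygen trace
        from oxyallo.synthdata import (Archetype, GroundTruth,
                                       synthesize_fluorescence)

        from oxyallo.signalproc import smooth_po2
        from oxyallo.synthdata import true_po2

        arch = Archetype("astro", n_cells=3, slow_coupling=0.0,
                         slow_shape="flat", fast_gain=0.3, ca_decay=3.0,
                         po2_gain=True)
        truth = GroundTruth(seed=5, archetypes=(arch,), fluo_noise=0.0)
        rec = small_exp.recording
        po2 = true_po2(truth, small_exp.bouts, short_schedule)
        fluo = synthesize_fluorescence(truth, small_exp.bouts, po2,
                                       short_schedule)
        f0 = fluo.F.min(axis=1, keepdims=True)  # noiseless flat baseline
        dff = (fluo.F / f0 - 1.0).mean(axis=0)
        fit = fit_gain_model(dff, fluo.frame_rate, small_exp.bouts,
                             smooth_po2(rec.po2_brain, rec.po2_fs),
                             rec.po2_fs, decay_grid=np.array([1.0, 3.0, 6.0]))
        blocks = fit.blocks.dropna()
        assert len(blocks) > 5
        r = np.corrcoef(blocks["gain"], 8.0 / blocks["po2_mean"])[0, 1]
        assert r > 0.9
        # monotone decreasing in pO2
        lo = blocks[blocks.po2_mean < blocks.po2_mean.median()]["gain"].mean()
        hi = blocks[blocks.po2_mean >= blocks.po2_mean.median()]["gain"].mean()
        assert lo > hi

    def test_zero_vigor_recording_empty(self):
        bouts = pd.DataFrame(columns=["onset_s", "offset_s", "vigor"])
        fit = fit_gain_model(np.zeros(600), 2.0, bouts, np.full(3000, 8.0),
                             po2_fs=10.0)
        assert len(fit.blocks) == 0


class TestSpikeVigorRegression:
    def test_noiseless_ratio_exact(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 5, 40)
        counts = np.concatenate([2.0 * v[:20], 5.0 * v[20:]])
        cond = np.array(["normoxia"] * 20 + ["hypoxia"] * 20)
        out = spike_vigor_regression(counts, np.concatenate([v[:20], v[20:]]),
                                     cond)
        assert out.attrs["slope_ratio"] == pytest.approx(0.4)

    def test_neuron_model_gain_ratio_recovered(self):
        # escape-rate neuron: spike counts per pulse scale with the oxygen
        # gate; planted rate ratio recovered within 20% at 200 trials
        from oxyallo.neuronmodel import LifParams, simulate_neuron

        rng = np.random.default_rng(1)
        params = LifParams(lambda0=5.0, pulse_amp=20.0, pulse_dur=0.05)
        counts, vigors, conds = [], [], []
        dt = 0.001
        for cond, po2_level in (("normoxia", 8.0), ("hypoxia", 4.0)):
            for _ in range(100):
                vigor = int(rng.integers(1, 11))
                n = int(1.5 / dt)
                po2 = np.full(n, po2_level)
                pulses = 0.1 + 0.1 * np.arange(vigor)
                _, spikes = simulate_neuron(params, po2, pulses, dt=dt,
                                            seed=int(rng.integers(2**31)))
                counts.append(spikes.size)
                vigors.append(vigor)
                conds.append(cond)
        out = spike_vigor_regression(np.array(counts), np.array(vigors),
                                     np.array(conds))
        # the oxygen gate multiplies the rate by exp(drive/delta_v)
        expected = np.exp(-params.o2_gain_mv * (8.0 / 4.0 - 1.0)
                          / params.delta_v)
        assert out.attrs["slope_ratio"] == pytest.approx(expected, rel=0.2)

    def test_shuffled_vigor_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(1, 5, 200)
        counts = rng.poisson(3.0, 200).astype(float)
        cond = np.array(["normoxia"] * 200)
        out = spike_vigor_regression(counts, v, cond)
        assert out.loc["normoxia", "ci_lo"] < 0 < out.loc["normoxia", "ci_hi"]

    def test_degenerate_vigor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            spike_vigor_regression(np.arange(20.0), np.ones(20),
                                   np.array(["normoxia"] * 20))
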