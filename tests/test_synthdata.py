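"""Synthetic-experiment generator: oxygen plant, channels, fluorescence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from oxyallo import synthdata
from oxyallo.paradigm import Epoch, Paradigm, default_paradigm
from oxyallo.synthdata import (
    Archetype,
    GroundTruth,
    O2System,
    rasterize_vigor,
    simulate_po2,
    synthesize_fluorescence,
    synthesize_recording,
)


def flat_schedule(level=8.0, duration=300.0):
    return Paradigm(epochs=(Epoch("normoxia", 0.0, duration, level),))


class TestParadigm:
    def test_epochs_must_be_contiguous(self):
        with pytest.raises(ValueError):
            Paradigm(
                epochs=(
                    Epoch("normoxia", 0.0, 10.0, 8.0),
                    Epoch("hypoxia", 20.0, 30.0, 4.0),
                )
            )

    def test_levels_positive(self):
        with pytest.raises(ValueError):
            Epoch("hypoxia", 0.0, 10.0, -1.0)

    def test_bath_step_settles_by_five_minutes(self):
        # the 8 -> 4 mg/L perfusate switch should be ~95% complete at 5 min
        sched = default_paradigm()
        t_switch = sched.epoch("hypoxia").start
        bath = sched.bath_trace(np.array([t_switch + 300.0]))
        completed = (8.0 - bath[0]) / 4.0
        assert completed >= 0.95

    def test_labels_and_targets(self):
        sched = default_paradigm()
        assert list(sched.label_at([100.0, 1500.0])) == ["normoxia", "hypoxia"]
        assert list(sched.target_at([100.0, 1500.0])) == [8.0, 4.0]


class TestSimulatePo2:
    def test_equilibrium_without_swimming(self):
        sched = flat_schedule()
        x, bath = simulate_po2(sched, np.zeros(3000), O2System(), dt=0.1)
        assert np.allclose(x, 8.0)
        assert np.allclose(bath, 8.0)

    def test_step_response_matches_closed_form(self):
        # constant bath, u steps to ubar at t0, no delay:
        # x(t) = bath - (beta*u/alpha)(1 - exp(-alpha (t - t0)))
        sys = O2System(alpha=0.1, beta=0.2, tau_d=0.0)
        dt, ubar, t0_idx = 0.1, 1.5, 500
        u = np.zeros(4000)
        u[t0_idx:] = ubar
        sched = flat_schedule(duration=400.0)
        x, _ = simulate_po2(sched, u, sys, dt=dt)
        t = np.arange(4000) * dt
        expect = np.where(
            t <= t0_idx * dt,
            8.0,
            8.0 - sys.beta * ubar / sys.alpha
            * (1 - np.exp(-sys.alpha * (t - t0_idx * dt))),
        )
        assert np.allclose(x, expect, atol=1e-6)

    @pytest.mark.parametrize(
        "bad", [np.array([1.0, np.nan]), np.array([1.0, -2.0])]
    )
    def test_invalid_vigor_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_po2(flat_schedule(), bad, O2System(), dt=0.1)

    def test_dt_must_divide_delay(self):
        with pytest.raises(ValueError):
            simulate_po2(flat_schedule(), np.zeros(10), O2System(tau_d=2.0),
                         dt=0.3)
        with pytest.raises(ValueError):
            simulate_po2(flat_schedule(), np.zeros(10), O2System(), dt=-0.1)

    def test_po2_stays_within_bath_bounds(self, small_exp, small_truth,
                                          short_schedule):
        true = synthdata.true_po2(small_truth, small_exp.bouts,
                                  short_schedule)
        assert true.min() >= 0.0
        assert true.max() <= 8.0 + 1e-9
        # the measured channel is noisy but still non-negative
        assert small_exp.recording.po2_brain.min() >= 0.0

    def test_delay_peak_in_cross_correlation(self):
        # noiseless: corr(vigor, -dx/dt) peaks at the motor-to-oxygen delay
        rng = np.random.default_rng(0)
        dt = 0.1
        sys = O2System(alpha=0.1, beta=0.2, tau_d=2.0)
        onsets = np.sort(rng.uniform(5, 280, 60))
        bouts = pd.DataFrame(
            {"onset_s": onsets, "offset_s": onsets + 0.2,
             "vigor": rng.uniform(0.5, 2, 60)}
        )
        u = rasterize_vigor(bouts, 300.0, dt)
        x, _ = simulate_po2(flat_schedule(), u, sys, dt=dt)
        ddt = -np.gradient(x, dt)
        lags = np.arange(0, 60)
        cc = [
            np.corrcoef(u[: u.size - k] if k else u, ddt[k:])[0, 1]
            for k in lags
        ]
        k_star = lags[int(np.argmax(cc))]
        assert abs(k_star * dt - sys.tau_d) <= dt + 1e-9


class TestSynthesizeRecording:
    def test_seed_determinism_bit_identical(self, short_schedule):
        truth = GroundTruth(seed=5)
        rec1, bouts1, man1 = synthesize_recording(truth, short_schedule)
        rec2, bouts2, man2 = synthesize_recording(truth, short_schedule)
        assert np.array_equal(rec1.swim, rec2.swim)
        assert np.array_equal(rec1.resp, rec2.resp)
        assert np.array_equal(rec1.po2_brain, rec2.po2_brain)
        pd.testing.assert_frame_equal(bouts1, bouts2)
        assert man1["resp_events"] == man2["resp_events"]

    def test_noiseless_burst_energy_scales_with_vigor(self, short_schedule):
        from oxyallo.signalproc import swim_power

        truth = GroundTruth(seed=0, swim_snr=np.inf)
        n = int(10.0 * truth.fs)
        for v, ref in [(1.0, None), (3.0, None)]:
            bouts = pd.DataFrame(
                {"onset_s": [2.0], "offset_s": [2.3], "vigor": [v]}
            )
            sig = synthdata._swim_channel(
                bouts, truth, n, np.random.default_rng(0)
            )
            energy = np.trapezoid(swim_power(sig, truth.fs), dx=1 / truth.fs)
            if v == 1.0:
                e1 = energy
        assert np.isclose(energy / e1, 3.0, rtol=1e-2)

    def test_circuit_generator_directional_behavior(self, small_exp,
                                                    short_schedule):
        bouts = small_exp.bouts
        lab = short_schedule.label_at(bouts["onset_s"].values)
        t_half = short_schedule.epoch("hypoxia").start
        rate_norm = np.sum(lab == "normoxia") / t_half
        rate_hyp = np.sum(lab == "hypoxia") / t_half
        assert rate_hyp < rate_norm
        resp = np.asarray(small_exp.resp_events)
        resp_norm = np.sum(resp < t_half) / t_half
        resp_hyp = np.sum(resp >= t_half) / t_half
        assert resp_hyp > resp_norm

    def test_overlapping_bouts_rejected(self, short_schedule):
        truth = GroundTruth(seed=0)
        bad = pd.DataFrame(
            {"onset_s": [1.0, 1.1], "offset_s": [1.5, 1.6], "vigor": [1, 1]}
        )
        with pytest.raises(ValueError, match="overlap"):
            synthdata._GENERATORS["circuit"] = lambda *a, **k: bad
            try:
                synthesize_recording(truth, short_schedule)
            finally:
                synthdata._GENERATORS["circuit"] = synthdata._generate_circuit

    @pytest.mark.parametrize("gen", ["reactive", "predictive_glm", "controller"])
    def test_other_generators_produce_bouts(self, gen, short_schedule):
        truth = GroundTruth(generator=gen, seed=2)
        rec, bouts, man = synthesize_recording(truth, short_schedule)
        assert len(bouts) > 20
        assert (bouts["offset_s"] > bouts["onset_s"]).all()
        assert man["generator"] == gen


class TestSynthesizeFluorescence:
    def test_zero_couplings_zero_noise_constant(self, short_schedule):
        arch = Archetype("null", n_cells=3, slow_coupling=0.0,
                         slow_shape="flat", fast_gain=0.0)
        truth = GroundTruth(seed=1, archetypes=(arch,), fluo_noise=0.0)
        bouts = pd.DataFrame({"onset_s": [10.0], "offset_s": [10.2],
                              "vigor": [1.0]})
        po2 = np.full(int(480 * truth.po2_fs), 8.0)
        fluo = synthesize_fluorescence(truth, bouts, po2, short_schedule)
        assert np.allclose(fluo.F, fluo.F[:, :1])

    def test_nts_baseline_tracks_hypoxia(self, short_schedule):
        from scipy.stats import spearmanr

        arch = Archetype("nts", n_cells=2, slow_coupling=0.5,
                         slow_shape="direct", fast_gain=0.0)
        truth = GroundTruth(seed=1, archetypes=(arch,), fluo_noise=0.0)
        t = np.arange(int(480 * truth.po2_fs)) / truth.po2_fs
        po2 = 8.0 - 4.0 * (t / t[-1])  # steady decline
        fluo = synthesize_fluorescence(truth, pd.DataFrame(
            columns=["onset_s", "offset_s", "vigor"]), po2, short_schedule)
        po2_f = np.interp(fluo.t, t, po2)
        r = spearmanr(fluo.F[0], -po2_f).statistic
        assert r > 0.9

    def test_po2_gain_ratio_matches_programmed(self, short_schedule):
        # identical bouts in normoxia vs hypoxia: transient ratio equals the
        # po2_norm/po2 gain ratio, verified against a direct convolution
        arch = Archetype("astro", n_cells=1, slow_coupling=0.0,
                         slow_shape="flat", fast_gain=0.3, ca_decay=4.0,
                         po2_gain=True)
        truth = GroundTruth(seed=4, archetypes=(arch,), fluo_noise=0.0)
        fr = truth.frame_rate
        bouts = pd.DataFrame(
            {"onset_s": [100.0, 340.0], "offset_s": [100.2, 340.2],
             "vigor": [2.0, 2.0]}
        )
        po2 = np.where(np.arange(int(480 * truth.po2_fs)) / truth.po2_fs < 240,
                       8.0, 4.0)
        fluo = synthesize_fluorescence(truth, bouts, po2, short_schedule)
        dff = fluo.F[0] / fluo.F[0, 0] - 1.0
        peak_norm = dff[int(100 * fr) : int(110 * fr)].max()
        peak_hyp = dff[int(340 * fr) : int(350 * fr)].max()
        assert np.isclose(peak_hyp / peak_norm, 2.0, rtol=1e-6)
        # direct convolution oracle for the normoxia transient
        n = fluo.F.shape[1]
        impulse = np.zeros(n)
        impulse[int(100.0 * fr)] = 2.0 * (8.0 / 8.0)
        impulse[int(340.0 * fr)] = 2.0 * (8.0 / 4.0)
        kern = np.exp(-np.arange(int(5 * 4.0 * fr) + 1) / (4.0 * fr))
        gain = fluo.F[0, int(100 * fr) + 1] / fluo.F[0, 0] - 1.0
        expected = np.convolve(impulse, kern)[:n]
        scale = gain / expected[int(100 * fr) + 1]
        assert np.allclose(dff, scale * expected, atol=1e-9)

    def test_non_positive_baseline_rejected(self, short_schedule):
        arch = Archetype("bad", n_cells=1, slow_coupling=-3.0,
                         slow_shape="direct")
        truth = GroundTruth(seed=1, archetypes=(arch,), fluo_noise=0.0)
        po2 = np.full(int(480 * truth.po2_fs), 2.0)  # deep hypoxia
        with pytest.raises(ValueError, match="non-positive baseline"):
            synthesize_fluorescence(
                truth, pd.DataFrame(columns=["onset_s", "offset_s", "vigor"]),
                po2, short_schedule)

    def test_bouts_outside_span_rejected(self, short_schedule):
        truth = GroundTruth(seed=1)
        bouts = pd.DataFrame({"onset_s": [1000.0], "offset_s": [1000.2],
                              "vigor": [1.0]})
        with pytest.raises(ValueError, match="past the recording"):
            synthesize_fluorescence(truth, bouts,
                                    np.full(4800, 8.0), short_schedule)

    def test_fluorescence_always_positive(self, small_exp):
        assert small_exp.fluo.F.min() > 0


class TestManifest:
    def test_manifest_records_seed_and_truth(self, small_exp, small_truth):
        man = small_exp.manifest
        assert man["seed"] == small_truth.seed
        assert man["generator"] == "circuit"
        assert man["o2"] == dataclasses.asdict(small_truth.o2)
        assert len(man["bouts"]["onset_s"]) == len(small_exp.bouts)
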