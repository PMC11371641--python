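import math

import numpy as np
import pytest

from epsckit import evoked as ev
from epsckit import synthgen as sg
from epsckit.traceio import AnalysisConfig, Polarity, Trace, WindowError


def flat_trace(value=0.0, n=10_000, sr=10_000.0, **kw):
    return Trace(samples=np.full(n, value), sampling_rate=sr, **kw)


def positive_trace(samples, sr=10_000.0, **kw):
    return Trace(samples=np.asarray(samples, float), sampling_rate=sr,
                 polarity=Polarity.POSITIVE_UP, **kw)


class TestPreprocess:
    def test_constant_holding_current_removed(self):
        p = ev.preprocess(flat_trace(-50.0))
        assert np.allclose(p.samples, 0.0)
        assert float(p.annotations["baseline_pA"]) == pytest.approx(-50.0)
        assert p.polarity is Polarity.POSITIVE_UP

    def test_amplitude_invariant_to_holding_offset(self):
        cfg = sg.preset_config("WT", "epsc", seed=2, noise_sd=0.0)
        trace, _ = sg.simulate_evoked_epsc(cfg)
        shifted = Trace(samples=trace.samples - 30.0,
                        sampling_rate=trace.sampling_rate,
                        polarity=trace.polarity,
                        stimulus_times=trace.stimulus_times,
                        annotations=trace.annotations)
        m0 = ev.epsc_metrics(ev.preprocess(trace), 0.2)
        m1 = ev.epsc_metrics(ev.preprocess(shifted), 0.2)
        assert m1.amplitude == pytest.approx(m0.amplitude, rel=1e-9)

    def test_noise_only_baseline_within_sampling_bound(self):
        rng = np.random.default_rng(5)
        sd, n_base = 2.0, 500  # 50 ms baseline window at 10 kHz
        trace = Trace(samples=rng.normal(-10.0, sd, 20_000),
                      sampling_rate=10_000.0, stimulus_times=[0.5])
        p = ev.preprocess(trace)
        baseline = float(p.annotations["baseline_pA"])
        assert abs(baseline - (-10.0)) < 3.0 * sd / math.sqrt(n_base)

    def test_baseline_window_before_start_rejected(self):
        trace = flat_trace(stimulus_times=[0.001])
        with pytest.raises(WindowError):
            ev.preprocess(trace)


class TestEpscMetrics:
    def test_single_quantum_amplitude_and_peak_time(self, kernel):
        x = np.zeros(10_000)
        onset = 2010  # stimulus at 0.2 s, latency 1 ms
        x[onset:onset + kernel.samples.size] = -kernel.samples
        trace = Trace(samples=x, sampling_rate=10_000.0, stimulus_times=[0.2])
        m = ev.epsc_metrics(ev.preprocess(trace), 0.2)
        assert m.amplitude == pytest.approx(20.0, rel=0.01)
        assert m.time_to_peak == pytest.approx(1.0 + kernel.peak_time, abs=0.15)

    def test_rectangular_pulse_charge(self):
        x = np.zeros(10_000)
        x[2000:2100] = 100.0  # 100 pA for 10 ms
        trace = positive_trace(x, stimulus_times=[0.2])
        m = ev.epsc_metrics(trace, 0.2)
        assert m.charge == pytest.approx(1.0, rel=0.02)

    def test_zero_trace(self):
        m = ev.epsc_metrics(positive_trace(np.zeros(10_000),
                                           stimulus_times=[0.2]), 0.2)
        assert m.amplitude == 0.0
        assert m.charge == 0.0

    def test_empty_window_rejected(self):
        trace = positive_trace(np.zeros(100))
        with pytest.raises(WindowError):
            ev.epsc_metrics(trace, 0.5)


class TestBiexpFit:
    sr = 10_000.0

    def _trace_from_decay(self, y):
        return positive_trace(y, sr=self.sr)

    def test_known_biexponential_recovered_exactly(self):
        t = np.arange(0, 0.5, 1 / self.sr) * 1000.0
        y = 1000.0 * np.exp(-t / 5.0) + 100.0 * np.exp(-t / 50.0)
        fit = ev.fit_biexp_decay(self._trace_from_decay(y), 0.0)
        assert fit.converged
        assert fit.A_fast == pytest.approx(1000.0, rel=0.01)
        assert fit.tau_fast == pytest.approx(5.0, rel=0.01)
        assert fit.A_slow == pytest.approx(100.0, rel=0.01)
        assert fit.tau_slow == pytest.approx(50.0, rel=0.01)

    def test_mono_exponential_degenerates_cleanly(self):
        t = np.arange(0, 0.5, 1 / self.sr) * 1000.0
        y = 500.0 * np.exp(-t / 8.0)
        fit = ev.fit_biexp_decay(self._trace_from_decay(y), 0.0)
        total = fit.A_fast * fit.tau_fast + fit.A_slow * fit.tau_slow
        assert fit.A_slow * fit.tau_slow < 0.01 * total
        assert fit.tau_fast == pytest.approx(8.0, rel=0.01)
        assert fit.tau_slow > fit.tau_fast

    def test_noisy_recovery_median_within_five_percent(self):
        t = np.arange(0, 0.5, 1 / self.sr) * 1000.0
        clean = 1000.0 * np.exp(-t / 5.0) + 100.0 * np.exp(-t / 50.0)
        errs = []
        for seed in range(8):
            y = clean + np.random.default_rng(seed).normal(0, 5.0, t.size)
            fit = ev.fit_biexp_decay(self._trace_from_decay(y), 0.0)
            errs.append([abs(fit.A_fast / 1000 - 1), abs(fit.tau_fast / 5 - 1),
                         abs(fit.A_slow / 100 - 1), abs(fit.tau_slow / 50 - 1)])
        assert np.all(np.median(errs, axis=0) < 0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(ev.FitError):
            ev.fit_biexp_decay(positive_trace(np.ones(8), sr=10_000.0), 0.0,
                               window_end=8 / 10_000.0)


class TestDecomposition:
    def test_closed_form_example(self):
        fit = ev.EPSCDecayFit(A_fast=1000.0, tau_fast=5.0, A_slow=100.0,
                              tau_slow=50.0, fit_rmse=0.0, converged=True)
        sync, async_, frac = ev.decompose_sync_async(fit, rise_charge=0.2)
        assert sync == pytest.approx(5.2)
        assert async_ == pytest.approx(5.0)
        assert frac == pytest.approx(5.0 / 10.2, abs=1e-12)

    def test_no_slow_component_gives_zero_fraction(self):
        fit = ev.EPSCDecayFit(A_fast=500.0, tau_fast=5.0, A_slow=0.0,
                              tau_slow=50.0, fit_rmse=0.0, converged=True)
        _, _, frac = ev.decompose_sync_async(fit, 0.1)
        assert frac == 0.0

    def test_equal_charges_without_rise_gives_half(self):
        fit = ev.EPSCDecayFit(A_fast=1000.0, tau_fast=5.0, A_slow=100.0,
                              tau_slow=50.0, fit_rmse=0.0, converged=True)
        _, _, frac = ev.decompose_sync_async(fit, 0.0)
        assert frac == pytest.approx(0.5)

    def test_zero_charges_undefined(self):
        fit = ev.EPSCDecayFit(A_fast=0.0, tau_fast=5.0, A_slow=0.0,
                              tau_slow=50.0, fit_rmse=0.0, converged=True)
        _, _, frac = ev.decompose_sync_async(fit, 0.0)
        assert math.isnan(frac)

    def test_charge_additivity_end_to_end(self):
        cfg = sg.preset_config("PL", "epsc", seed=3, noise_sd=0.0)
        trace, _ = sg.simulate_evoked_epsc(cfg)
        m, fit = ev.analyze_epsc(ev.preprocess(trace))
        # sync+async (analytic) vs measured trace charge over the window
        assert (fit.sync_charge + fit.async_charge
                == pytest.approx(m.charge, rel=0.02))


class TestPairedPulse:
    def test_identical_responses_give_unity(self, kernel):
        x = np.zeros(20_000)
        for onset in (2010, 7010):  # 0.5 s apart: full recovery
            x[onset:onset + kernel.samples.size] -= 50 * kernel.samples
        trace = Trace(samples=x, sampling_rate=10_000.0,
                      stimulus_times=[0.2, 0.7])
        ppr = ev.paired_pulse_ratio(ev.preprocess(trace))
        assert ppr == pytest.approx(1.0, rel=0.01)

    def test_expected_value_depletion_gives_one_minus_p(self):
        cfg = sg.SimulationConfig(seed=0, release_fraction=0.5,
                                  recruitment_rate=0.0, async_count_mean=0.0,
                                  noise_sd=0.0, expected_value_mode=True,
                                  stimulus_times=(0.2, 0.25))
        trace, _ = sg.simulate_train(cfg, duration=1.0)
        ppr = ev.paired_pulse_ratio(ev.preprocess(trace))
        assert ppr == pytest.approx(0.5, abs=0.01)

    def test_silent_second_pulse(self, kernel):
        x = np.zeros(20_000)
        x[2010:2010 + kernel.samples.size] -= 50 * kernel.samples
        trace = Trace(samples=x, sampling_rate=10_000.0,
                      stimulus_times=[0.2, 0.7])
        assert ev.paired_pulse_ratio(ev.preprocess(trace)) == pytest.approx(
            0.0, abs=0.02)

    def test_ppr_invariant_to_quantal_scaling(self):
        base = sg.SimulationConfig(seed=9, noise_sd=0.0,
                                   stimulus_times=(0.2, 0.25))
        r1 = ev.paired_pulse_ratio(
            ev.preprocess(sg.simulate_train(base, duration=1.0)[0]))
        r2 = ev.paired_pulse_ratio(ev.preprocess(
            sg.simulate_train(base.replace(quantal_amplitude=60.0),
                              duration=1.0)[0]))
        assert r2 == pytest.approx(r1, rel=1e-6)

    def test_absent_first_response_is_nan(self):
        trace = positive_trace(np.zeros(20_000), stimulus_times=[0.2, 0.7])
        assert math.isnan(ev.paired_pulse_ratio(trace))


class TestTrainAnalysis:
    def test_clean_synchronous_train_flat_and_synchronous(self):
        cfg = sg.preset_config("WT", "train20", noise_sd=0.0,
                               expected_value_mode=True, async_count_mean=0.0,
                               release_fraction=0.1, recruitment_rate=10_000.0)
        trace, _ = sg.simulate_train(cfg)
        res = ev.analyze_train(ev.preprocess(trace))
        assert np.all(np.abs(res.normalized_amplitudes - 1.0) < 0.02)
        assert res.train_async_fraction < 0.02

    def test_async_fraction_recovery_against_ground_truth(self):
        fracs = []
        for s in range(6):
            cfg = sg.preset_config("PL", "train20", seed=s, tau_async=300.0)
            trace, gt = sg.simulate_train(cfg)
            res = ev.analyze_train(ev.preprocess(trace))
            fracs.append(res.train_async_fraction - gt.true_async_fraction)
        assert abs(np.mean(fracs)) < 0.05

    def test_tail_decay_constant_self_fit(self):
        cfg = sg.preset_config("WT", "train20", noise_sd=0.0,
                               expected_value_mode=True, tau_async=200.0)
        trace, _ = sg.simulate_train(cfg)
        res = ev.analyze_train(ev.preprocess(trace))
        assert res.tail_tau == pytest.approx(200.0, rel=0.05)

    def test_fraction_bounds(self):
        for s in range(3):
            cfg = sg.preset_config("PL", "train20", seed=s)
            trace, _ = sg.simulate_train(cfg)
            res = ev.analyze_train(ev.preprocess(trace))
            assert 0.0 <= res.train_async_fraction <= 1.0

    def test_async_share_ladder_is_monotone(self):
        recovered = []
        for share in (0.0, 0.1, 0.3, 0.5):
            acm = 150.0 * share / (1.0 - share) if share < 1 else 0.0
            cfg = sg.preset_config("WT", "train20", noise_sd=0.0,
                                   expected_value_mode=True,
                                   async_count_mean=acm, tau_async=300.0)
            trace, _ = sg.simulate_train(cfg)
            res = ev.analyze_train(ev.preprocess(trace))
            recovered.append(res.train_async_fraction)
        assert np.all(np.diff(recovered) > 0)


class TestBackExtrapolation:
    def test_constant_release_gives_exact_line(self):
        # constant 1 pC per pulse at 40 Hz: y = 1 + 40 t exactly
        stims = 0.2 + 0.025 * np.arange(40)
        res = ev.TrainResult(
            pulse_amplitudes=np.ones(40), normalized_amplitudes=np.ones(40),
            per_pulse_charges=np.ones(40), total_charge=40.0,
            train_async_fraction=0.0, tail_tau=float("nan"), tail_charge=0.0)
        est = ev.backextrapolate_rrp(res, stims)
        assert est.rrp_charge == pytest.approx(1.0, abs=1e-9)
        assert est.recruitment_rate == pytest.approx(40.0, rel=1e-9)
        assert est.fit_r2 == pytest.approx(1.0)

    def test_all_zero_charges(self):
        stims = 0.2 + 0.025 * np.arange(40)
        res = ev.TrainResult(
            pulse_amplitudes=np.zeros(40), normalized_amplitudes=np.ones(40),
            per_pulse_charges=np.zeros(40), total_charge=0.0,
            train_async_fraction=float("nan"), tail_tau=float("nan"),
            tail_charge=0.0)
        est = ev.backextrapolate_rrp(res, stims)
        assert est.rrp_charge == 0.0
        assert est.recruitment_rate == 0.0

    def test_depletion_model_intercept_near_true_pool(self):
        cfg = sg.preset_config("WT", "train40", noise_sd=0.0,
                               expected_value_mode=True,
                               release_fraction=0.4, recruitment_rate=600.0)
        trace, gt = sg.simulate_train(cfg)
        res = ev.analyze_train(ev.preprocess(trace))
        est = ev.backextrapolate_rrp(res, trace.stimulus_times)
        assert est.rrp_charge == pytest.approx(gt.true_rrp_charge, rel=0.15)


class TestSucrose:
    def test_flat_trace_zero_rrp(self):
        trace = positive_trace(np.zeros(40_000))
        est = ev.estimate_rrp_sucrose(trace, (0.5, 3.0))
        assert est.rrp_charge == 0.0
        assert est.method == "sucrose"

    def test_noiseless_discharge_recovers_pool(self):
        cfg = sg.preset_config("WT", "sucrose", seed=4, noise_sd=0.0,
                               recruitment_rate=0.0)
        trace, gt = sg.simulate_sucrose(cfg, (0.5, 3.0))
        est = ev.estimate_rrp_sucrose(ev.preprocess(trace), (0.5, 3.0))
        assert est.rrp_charge == pytest.approx(gt.true_rrp_charge, rel=0.05)

    def test_pool_doubling_doubles_estimate(self):
        base = sg.preset_config("WT", "sucrose", seed=4, noise_sd=0.0,
                                recruitment_rate=0.0)
        est1 = ev.estimate_rrp_sucrose(ev.preprocess(
            sg.simulate_sucrose(base, (0.5, 3.0))[0]), (0.5, 3.0))
        est2 = ev.estimate_rrp_sucrose(ev.preprocess(
            sg.simulate_sucrose(base.replace(pool_size=1000), (0.5, 3.0))[0]),
            (0.5, 3.0))
        assert est2.rrp_charge == pytest.approx(2.0 * est1.rrp_charge, rel=0.05)

    def test_missing_window_metadata_rejected(self):
        from epsckit.traceio import MetadataError
        with pytest.raises(MetadataError):
            ev.estimate_rrp_sucrose(positive_trace(np.zeros(10_000)))

    def test_train_and_sucrose_estimates_agree(self):
        # constant-recruitment depletion model, matched configs
        cfg40 = sg.preset_config("WT", "train40", noise_sd=0.0,
                                 expected_value_mode=True)
        trace, _ = sg.simulate_train(cfg40)
        res = ev.analyze_train(ev.preprocess(trace))
        train_est = ev.backextrapolate_rrp(res, trace.stimulus_times)
        cfg_s = sg.preset_config("WT", "sucrose", noise_sd=0.0,
                                 expected_value_mode=True,
                                 recruitment_rate=0.0)
        trace_s, _ = sg.simulate_sucrose(cfg_s, (0.5, 3.0))
        suc_est = ev.estimate_rrp_sucrose(ev.preprocess(trace_s), (0.5, 3.0))
        assert train_est.rrp_charge == pytest.approx(suc_est.rrp_charge,
                                                     rel=0.20)


class TestRecoveryMonotonicity:
    def test_async_fraction_increases_with_generator_share(self):
        recovered = []
        for acm in (0.0, 10.0, 30.0, 60.0):
            cfg = sg.preset_config("WT", "epsc", noise_sd=0.0,
                                   expected_value_mode=True,
                                   async_count_mean=acm)
            trace, _ = sg.simulate_evoked_epsc(cfg)
            _, fit = ev.analyze_epsc(ev.preprocess(trace))
            recovered.append(fit.async_fraction)
        assert np.all(np.diff(recovered) > 0)
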