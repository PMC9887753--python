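"""Decay fitting, protocol segmentation, and the SERCA2/NCX decomposition."""

import numpy as np
import pytest

from catrace import (
    AnalysisParams,
    CaffeineNotFoundError,
    FitError,
    FluorescenceTrace,
    ProtocolDescriptor,
    SimConfig,
    analyze_trace,
    fit_exponential_decay,
    fractional_release,
    normalize_trace,
    segment_protocol,
    select_systolic_spike,
    serca_function,
    simulate_trace,
)
from catrace.pipeline import analyze_cohort, summaries_frame
from catrace.simulate import simulate_cohort
from catrace.spikes import Spike


from oracles import sse_oracle_fit_k


class TestFitDecay:
    def test_noiseless_closed_form_recovered_to_machine_precision(self):
        t = np.arange(98) / 97.0
        fit = fit_exponential_decay(t, 2.0 * np.exp(-3.0 * t))
        assert fit.converged
        assert fit.k == pytest.approx(3.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)

    def test_monte_carlo_error_distribution(self):
        """sd 0.02 noise on a unit-amplitude decay: median |rel err| <= 2%,
        95th percentile <= 10% (seeded replicate draw)."""
        t = np.arange(98) / 97.0
        clean = np.exp(-3.0 * t)
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(200):
            fit = fit_exponential_decay(t, clean + rng.normal(0, 0.02, t.size))
            errs.append(abs(fit.k - 3.0) / 3.0)
        errs = np.sort(errs)
        assert np.median(errs) <= 0.02
        assert np.quantile(errs, 0.95) <= 0.10

    def test_constant_segment_not_converged(self):
        t = np.arange(50) / 97.0
        fit = fit_exponential_decay(t, np.full(50, 0.3))
        assert not fit.converged

    def test_rising_segment_not_converged(self):
        t = np.arange(50) / 97.0
        fit = fit_exponential_decay(t, t.copy())
        assert not fit.converged

    def test_too_short_segment_rejected(self):
        with pytest.raises(FitError, match="points"):
            fit_exponential_decay(np.arange(3) / 97.0, np.ones(3))

    @pytest.mark.parametrize("k_true", [1.0, 5.0, 20.0])
    def test_matches_grid_search_bisection_oracle(self, k_true):
        t = np.arange(50) / 97.0
        y = 1.3 * np.exp(-k_true * t) + 0.1
        fit = fit_exponential_decay(t, y)
        k_oracle = sse_oracle_fit_k(t, y)
        assert fit.k == pytest.approx(k_oracle, rel=0.01)

    def test_tau_is_reciprocal_rate(self):
        t = np.arange(60) / 97.0
        fit = fit_exponential_decay(t, np.exp(-2.0 * t))
        assert fit.tau == pytest.approx(0.5, rel=1e-6)


class TestSelectSystolicSpike:
    def spikes(self, n):
        return [Spike(peak_index=i * 100 + 5, peak_time=i + 0.05,
                      onset_index=i * 100, onset_time=float(i), amplitude=1.0,
                      time_to_peak=0.05, rate_of_rise=20.0, baseline=0.0,
                      prominence=1.0, stimulus_index=i) for i in range(n)]

    def test_single_spike_returned_regardless_of_seed(self):
        one = self.spikes(1)
        for seed in (0, 1, 99):
            assert select_systolic_spike(one, seed) is one[0]

    def test_choice_reproducible_under_seed(self):
        pool = self.spikes(7)
        assert select_systolic_spike(pool, 42) is select_systolic_spike(pool, 42)

    def test_uniform_over_spikes(self):
        pool = self.spikes(4)
        counts = np.zeros(4)
        for seed in range(10_000):
            counts[select_systolic_spike(pool, seed).stimulus_index] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_empty_pool_rejected(self):
        with pytest.raises(FitError):
            select_systolic_spike([], 0)


class TestSegmentProtocol:
    def test_detected_caffeine_onset_matches_truth(self, short_cfg, short_trace):
        trace, truth = short_trace
        sub = FluorescenceTrace(trace.time, trace.value - short_cfg.background_level)
        nt = normalize_trace(sub)
        proto = ProtocolDescriptor(pacing_freq_hz=0.5, pacing_start_s=1.0,
                                   pacing_stop_s=short_cfg.paced_duration)
        phases = segment_protocol(nt, proto)
        dt = 1.0 / short_cfg.frame_rate
        assert abs(phases.caffeine[0] - truth.caffeine_onset) <= 3 * dt

    def test_descriptor_times_echoed_exactly(self, short_cfg, short_trace):
        trace, _ = short_trace
        sub = FluorescenceTrace(trace.time, trace.value - short_cfg.background_level)
        nt = normalize_trace(sub)
        proto = short_cfg.protocol()
        phases = segment_protocol(nt, proto)
        assert phases.paced[1] == proto.pacing_stop_s
        assert phases.caffeine[0] == proto.caffeine_s

    def test_trace_ending_at_pacing_stop_raises(self):
        cfg = SimConfig(frame_rate=100.0, noise_sd=0.0, amplitude_cv=0.0,
                        paced_duration=11.0, pause_duration=4.0, caffeine_duration=4.0)
        trace, _ = simulate_trace(cfg)
        stop_i = int(11.0 * 100)
        clipped = FluorescenceTrace(trace.time[:stop_i],
                                    trace.value[:stop_i] - cfg.background_level)
        nt = normalize_trace(clipped)
        proto = ProtocolDescriptor(pacing_freq_hz=0.5, pacing_start_s=1.0,
                                   pacing_stop_s=11.0)
        with pytest.raises(CaffeineNotFoundError):
            segment_protocol(nt, proto)


class TestCaffeineAnalysis:
    def test_noiseless_rates_recovered(self, short_cfg, short_trace):
        trace, truth = short_trace
        res = analyze_trace(trace, short_cfg.protocol(),
                            AnalysisParams(rng_seed=5, min_spikes=5),
                            background=short_cfg.background_level)
        assert res.caffeine is not None
        assert res.caffeine.stim_fit.k == pytest.approx(truth.k_sys_true, abs=0.05)
        assert res.caffeine.caf_fit.k == pytest.approx(truth.k_caf_true, abs=0.05)

    def test_equal_caffeine_and_paced_amplitudes_give_unit_ratio(self):
        cfg = SimConfig(frame_rate=100.0, noise_sd=0.0, amplitude_cv=0.0,
                        caffeine_amplitude=1.0, amplitude_mean=1.0,
                        paced_duration=21.0, pause_duration=8.0, caffeine_duration=8.0)
        trace, _ = simulate_trace(cfg)
        res = analyze_trace(trace, cfg.protocol(),
                            AnalysisParams(rng_seed=5, min_spikes=5),
                            background=cfg.background_level)
        assert res.summary.fractional_release == pytest.approx(1.0, abs=0.01)

    def test_missing_caffeine_phase_flagged(self):
        cfg = SimConfig(frame_rate=100.0, noise_sd=0.0, amplitude_cv=0.0,
                        paced_duration=11.0, pause_duration=4.0, caffeine_duration=4.0)
        trace, _ = simulate_trace(cfg)
        stop_i = int(11.0 * 100)
        clipped = FluorescenceTrace(trace.time[:stop_i], trace.value[:stop_i])
        proto = ProtocolDescriptor(pacing_freq_hz=0.5, pacing_start_s=1.0,
                                   pacing_stop_s=11.0)
        with pytest.raises(CaffeineNotFoundError):
            analyze_trace(clipped, proto, AnalysisParams(rng_seed=5, min_spikes=5),
                          background=cfg.background_level)


class TestDerivedQuantities:
    def test_serca_function_is_rate_difference(self):
        assert serca_function(5.0, 2.0) == 3.0
        assert serca_function(4.2, 4.2) == 0.0

    def test_serca_function_rejects_non_finite(self):
        with pytest.raises(FitError):
            serca_function(np.nan, 1.0)

    def test_fractional_release_ratio(self):
        assert fractional_release(0.6, 1.2) == 0.5
        assert fractional_release(0.9, 0.9) == 1.0

    def test_fractional_release_requires_positive_amplitudes(self):
        with pytest.raises(FitError):
            fractional_release(0.0, 1.0)
        with pytest.raises(FitError):
            fractional_release(1.0, -2.0)


class TestCohortRecovery:
    def test_parameter_recovery_on_small_cohort(self):
        """12 cells at SNR 20: cohort means of SERCA2 function, caffeine rate
        and fractional release land within 10% / 10% / 5% of truth."""
        base = SimConfig()  # defaults: k_serca 3.5, k_ncx 1.5, SNR 20
        recs = simulate_cohort(base, 6, seed=17, jitter_cv=0.0)
        df = summaries_frame(analyze_cohort(recs, AnalysisParams(rng_seed=23)))
        assert df.eligible.all()
        assert df.serca_function.mean() == pytest.approx(3.5, rel=0.10)
        assert df.k_caf.mean() == pytest.approx(1.5, rel=0.10)
        assert df.fractional_release.mean() == pytest.approx(0.8, rel=0.05)

    def test_summary_rows_preserve_groups_and_identity(self):
        base = SimConfig(paced_duration=21.0, pause_duration=8.0,
                         caffeine_duration=8.0)
        recs = simulate_cohort(base, 2, seed=4, jitter_cv=0.0)
        analyses = analyze_cohort(recs, AnalysisParams(rng_seed=2, min_spikes=5))
        df = summaries_frame(analyses)
        assert len(df) == 4
        assert set(df.group) == {"group1", "group2"}
        ok = df.dropna(subset=["serca_function"])
        # identity holds bit-exactly on every converged row
        assert (ok.serca_function == ok.k_sys - ok.k_caf).all()

    def test_ineligible_cell_has_null_kinetics_and_reasons(self):
        base = SimConfig(paced_duration=21.0, pause_duration=8.0,
                         caffeine_duration=8.0)
        recs = simulate_cohort(base, 1, seed=4, jitter_cv=0.0)
        # default min_spikes=30 but only 10 stimuli fit in 21 s at 0.5 Hz
        analyses = analyze_cohort(recs, AnalysisParams(rng_seed=2))
        for a in analyses:
            assert not a.summary.qc.eligible
            assert a.summary.qc.reasons
            assert a.summary.serca_function is None
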