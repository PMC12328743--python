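"""Filtering, step detection and conductance statistics."""

import numpy as np
import pytest
from scipy import signal

from porescribe import (
    CurrentTrace,
    StepEvent,
    StepEventSet,
    TraceSimConfig,
    bessel_lowpass,
    conductance_of_events,
    detect_steps,
    event_statistics,
    robust_noise_sd,
    seal_check,
    simulate_trace,
)


def _sine_trace(freq_hz, fs=25000.0, duration=1.0, amplitude=100.0):
    t = np.arange(int(fs * duration)) / fs
    return CurrentTrace(amplitude * np.sin(2 * np.pi * freq_hz * t), fs, 50.0)


def _steady_amplitude(samples, fs):
    # RMS over the second half, past the filter transient
    tail = samples[samples.size // 2 :]
    return np.sqrt(2) * np.sqrt(np.mean(tail**2))


class TestBesselLowpass:
    def test_dc_gain_is_unity(self):
        trace = CurrentTrace(np.full(5000, 123.4), 5000.0, 50.0)
        out = bessel_lowpass(trace, 1000.0)
        assert np.allclose(out.samples[500:], 123.4, atol=1e-9)

    def test_attenuation_at_cutoff_matches_transfer_function(self):
        # independent oracle: analog order-8 Bessel prototype magnitude at
        # its cutoff (magnitude-normalised design: -3 dB)
        z, p, k = signal.besselap(8, norm="mag")
        expected = abs(k / np.prod(1j * 1.0 - p))
        trace = _sine_trace(1000.0)
        out = bessel_lowpass(trace, 1000.0)
        measured = _steady_amplitude(out.samples, 25000.0) / 100.0
        assert measured == pytest.approx(expected, rel=0.02)

    def test_double_pass_squares_the_response(self):
        trace = _sine_trace(1000.0)
        once = bessel_lowpass(trace, 1000.0)
        twice = bessel_lowpass(once, 1000.0)
        a1 = _steady_amplitude(once.samples, 25000.0)
        a2 = _steady_amplitude(twice.samples, 25000.0)
        assert a2 / 100.0 == pytest.approx((a1 / 100.0) ** 2, rel=0.02)

    def test_filter_history_appends(self):
        trace = CurrentTrace(np.zeros(100), 5000.0, 50.0)
        out = bessel_lowpass(bessel_lowpass(trace, 1000.0), 500.0)
        assert [h["cutoff_hz"] for h in out.filter_history] == [1000.0, 500.0]

    def test_cutoff_at_nyquist_rejected(self):
        trace = CurrentTrace(np.zeros(100), 2000.0, 50.0)
        with pytest.raises(ValueError):
            bessel_lowpass(trace, 1000.0)


class TestDetectSteps:
    def test_clean_staircase_exact(self, staircase_trace):
        events = detect_steps(staircase_trace)
        assert events.n == 5
        assert np.allclose(events.amplitudes_pA, 50.0, atol=1e-9)
        # step times at the 1 s plateau boundaries
        assert np.allclose(events.times, [1, 2, 3, 4, 5], atol=0.01)

    def test_dc_offset_invariance(self, staircase_trace):
        shifted = CurrentTrace(
            staircase_trace.samples + 500.0,
            staircase_trace.sampling_rate_hz,
            staircase_trace.holding_voltage_mV,
        )
        a = detect_steps(staircase_trace)
        b = detect_steps(shifted)
        assert a.n == b.n
        assert np.allclose(a.amplitudes_pA, b.amplitudes_pA, atol=1e-9)

    def test_downsampling_preserves_events(self, staircase_trace):
        down = CurrentTrace(
            staircase_trace.samples[::2],
            staircase_trace.sampling_rate_hz / 2,
            staircase_trace.holding_voltage_mV,
        )
        a = detect_steps(staircase_trace)
        b = detect_steps(down)
        assert a.n == b.n
        assert np.allclose(a.amplitudes_pA, b.amplitudes_pA, atol=1e-9)

    def test_recall_precision_on_simulated_traces(self):
        # SNR >= 5 regime over 5 seeds (the full 20-seed sweep runs in the
        # acceptance suite)
        recalls, precisions = [], []
        for seed in range(5):
            cfg = TraceSimConfig(seed=seed)
            raw, truth = simulate_trace(cfg)
            events = detect_steps(bessel_lowpass(raw))
            matched = _match(events.times, truth.event_times_s, tol=0.002)
            recalls.append(matched / max(1, truth.n_events))
            precisions.append(matched / max(1, events.n))
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_false_positive_rate_on_pure_noise(self):
        false_counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 10.0, 5000 * 60)
            trace = CurrentTrace(noise, 5000.0, 50.0)
            events = detect_steps(trace, min_step_pA=60.0)
            false_counts.append(events.n)
        assert np.mean(false_counts) < 1.0  # per 60 s

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_steps(CurrentTrace(np.zeros(50), 5000.0, 50.0), window=50)


def _match(detected, truth, tol):
    used = set()
    hits = 0
    for t in truth:
        for j, d in enumerate(detected):
            if j not in used and abs(d - t) <= tol:
                used.add(j)
                hits += 1
                break
    return hits


class TestConservation:
    def test_noiseless_sum_equals_plateau(self):
        cfg = TraceSimConfig(duration_s=30.0, baseline_noise_sd_pA=0.0, seed=8)
        raw, truth = simulate_trace(cfg)
        events = detect_steps(raw)
        final_g = raw.samples[-1] / cfg.holding_voltage_mV
        assert events.conductances_nS.sum() == pytest.approx(final_g, rel=1e-6)

    def test_noisy_sum_within_five_percent(self):
        errors = []
        for seed in range(5):
            cfg = TraceSimConfig(seed=seed)
            raw, truth = simulate_trace(cfg)
            events = detect_steps(bessel_lowpass(raw))
            total = events.conductances_nS.sum()
            # final plateau: samples after the last insertion settles
            start = int(truth.event_times_s[-1] * cfg.sampling_rate_hz) + 100
            if raw.samples.size - start < 500:
                continue
            plateau = np.mean(raw.samples[start:]) / cfg.holding_voltage_mV
            errors.append(abs(total - plateau) / plateau)
        assert np.mean(errors) <= 0.05


class TestEventStatistics:
    @staticmethod
    def _events(conductances):
        v = 50.0
        return StepEventSet(
            tuple(StepEvent(float(i), g * v, g) for i, g in enumerate(conductances)),
            v,
        )

    def test_small_multiset(self):
        stats = event_statistics(self._events([1.0, 2.0, 3.0]), bin_width_nS=1.0)
        assert stats.median_nS == 2.0
        assert stats.n == 3

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.lognormal(1.0, 0.5, size=rng.integers(1, 40))
            stats = event_statistics(self._events(g), 1.0)
            assert stats.median_nS == np.sort(g)[(g.size - 1) // 2]

    def test_lognormal_sample_median_near_population_median(self):
        rng = np.random.default_rng(123)
        g = rng.lognormal(np.log(10.8), 0.5, size=10_000)
        stats = event_statistics(self._events(g), 2.0)
        assert stats.median_nS == pytest.approx(10.8, rel=0.03)

    def test_histogram_counts_conserved(self):
        rng = np.random.default_rng(5)
        g = rng.lognormal(2.0, 0.8, size=500)
        stats = event_statistics(self._events(g), 2.0)
        assert stats.counts.sum() == 500

    def test_empty_set_flagged(self):
        stats = event_statistics(self._events([]), 1.0)
        assert stats.n == 0 and stats.median_nS is None


class TestConductanceOfEvents:
    def test_division_and_sign(self):
        events = StepEventSet((StepEvent(0.0, 540.0),), 50.0)
        out = conductance_of_events(events)
        assert out.events[0].delta_nS == pytest.approx(10.8)
        neg = conductance_of_events(StepEventSet((StepEvent(0.0, -540.0),), -50.0))
        assert neg.events[0].delta_nS == pytest.approx(10.8)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            conductance_of_events(StepEventSet((StepEvent(0.0, 1.0),), 0.0))


class TestSealCheck:
    def test_silent_membrane_passes(self):
        trace = CurrentTrace(np.zeros(3000), 5000.0, 0.0)
        result = seal_check(trace, [-50.0, 0.0, 50.0])
        assert result.conductance_nS == pytest.approx(0.0, abs=1e-12)
        assert result.passed

    def test_injected_leak_recovered_and_fails(self):
        # 10 pS leak: I = 0.01 nS * V per segment, plus noise
        rng = np.random.default_rng(3)
        voltages = [-50.0, -25.0, 0.0, 25.0, 50.0]
        segs = [0.01 * v + rng.normal(0, 0.05, 2000) for v in voltages]
        trace = CurrentTrace(np.concatenate(segs), 5000.0, 0.0)
        result = seal_check(trace, voltages, threshold_nS=0.001)
        assert result.conductance_nS == pytest.approx(0.01, rel=0.05)
        assert not result.passed

    def test_single_voltage_rejected(self):
        trace = CurrentTrace(np.zeros(100), 5000.0, 0.0)
        with pytest.raises(ValueError):
            seal_check(trace, [10.0])
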