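"""Ripple detection: envelope properties, thresholding rules, summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swrlab import swr
from swrlab.synthetic import LfpSimConfig, simulate_lfp
from swrlab.types import LfpTrace, SwrEvent


def _inject_burst(samples, fs, center_s, dur_ms, amp, freq=200.0):
    dur = int(dur_ms * fs / 1000.0)
    start = int(center_s * fs) - dur // 2
    t = np.arange(dur) / fs
    samples[start : start + dur] += amp * np.hanning(dur) * np.sin(2 * np.pi * freq * t)
    return samples


class TestRippleEnvelope:
    def test_zero_mean_unit_sd(self, standard_lfp):
        trace, _ = standard_lfp
        env = swr.ripple_envelope(trace)
        assert abs(env.mean()) < 1e-6
        assert env.std() == pytest.approx(1.0, abs=1e-6)

    def test_pure_tone_envelope_flat(self):
        """Analytic-signal identity: |H(a sin)| = a away from edges."""
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        trace = LfpTrace(samples=30.0 * np.sin(2 * np.pi * 200.0 * t), sampling_rate=fs)
        from scipy.signal import hilbert

        from swrlab import spectral

        filtered = spectral.band_filter(spectral.notch_60(trace), 150.0, 250.0)
        env = np.abs(hilbert(filtered.samples))
        core = env[2000:-2000]
        assert np.all(np.abs(core - 30.0) / 30.0 < 0.02)

    def test_white_noise_rarely_exceeds_three_sd(self):
        rng = np.random.default_rng(11)
        trace = LfpTrace(samples=rng.normal(size=60_000), sampling_rate=1000.0)
        env = swr.ripple_envelope(trace)
        assert (env > 3.0).mean() < 0.01

    def test_constant_trace_rejected(self):
        trace = LfpTrace(samples=np.full(5000, 3.3), sampling_rate=1000.0)
        with pytest.raises(ValueError, match="variance"):
            swr.ripple_envelope(trace)


class TestDetectSwr:
    def test_flat_envelope_no_events(self):
        assert swr.detect_swr(np.zeros(10_000), 1000.0) == []

    @staticmethod
    def _noise_and_envelope_sd(seed=5, fs=1000.0, scale=2.0):
        """White-noise background and its ripple-band envelope SD."""
        from scipy.signal import hilbert

        from swrlab import spectral

        rng = np.random.default_rng(seed)
        x = rng.normal(scale=scale, size=int(60 * fs))
        quiet = LfpTrace(samples=x.copy(), sampling_rate=fs)
        filtered = spectral.band_filter(spectral.notch_60(quiet), 150.0, 250.0)
        return x, float(np.abs(hilbert(filtered.samples)).std())

    def test_single_injected_ripple_detected(self):
        """A 50 ms ripple at 10x the envelope noise SD yields one event."""
        fs = 1000.0
        x, env_sd = self._noise_and_envelope_sd()
        _inject_burst(x, fs, center_s=30.0, dur_ms=50.0, amp=10.0 * env_sd)
        trace = LfpTrace(samples=x, sampling_rate=fs)
        events = swr.detect_swr_trace(trace)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset < 30.0 < ev.offset  # overlaps the truth interval

    def test_short_burst_rejected_by_duration_gate(self):
        """A 10 ms burst at the same amplitude fails the 15 ms minimum."""
        fs = 1000.0
        x, env_sd = self._noise_and_envelope_sd()
        _inject_burst(x, fs, center_s=30.0, dur_ms=10.0, amp=10.0 * env_sd)
        events = swr.detect_swr_trace(LfpTrace(samples=x, sampling_rate=fs))
        assert events == []

    def test_threshold_monotonicity(self, standard_lfp):
        trace, _ = standard_lfp
        env = swr.ripple_envelope(trace)
        counts = [
            len(swr.detect_swr(env, trace.sampling_rate, threshold_sd=th))
            for th in (2.0, 3.0, 4.0, 5.0, 7.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_amplitude_scale_invariance(self, standard_lfp):
        trace, _ = standard_lfp
        scaled = dataclasses.replace(trace, samples=trace.samples * 12.5)
        ev1 = swr.detect_swr_trace(trace)
        ev2 = swr.detect_swr_trace(scaled)
        assert [(e.onset, e.offset) for e in ev1] == [(e.onset, e.offset) for e in ev2]

    @given(seed=st.integers(0, 30))
    def test_duration_gate_fuzzed(self, seed):
        """No returned event is ever shorter than the minimum duration."""
        rng = np.random.default_rng(seed)
        env = rng.normal(size=8000) * rng.uniform(0.5, 2.0)
        env = (env - env.mean()) / env.std()
        events = swr.detect_swr(env, 1000.0, min_duration_ms=15.0, boundary_sd=3.0)
        for ev in events:
            assert ev.duration_ms >= 15.0

    def test_events_sorted_nonoverlapping(self, standard_lfp):
        trace, _ = standard_lfp
        events = swr.detect_swr_trace(trace)
        for a, b in zip(events, events[1:]):
            assert a.offset <= b.onset

    def test_oracle_recovery_on_simulated_trial(self, standard_lfp):
        trace, truth = standard_lfp
        events = swr.detect_swr_trace(trace)
        tp, fp, fn = swr.match_events(events, truth.events)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9


class TestWindowSlice:
    def _events(self, onsets):
        return [
            SwrEvent(onset=o, offset=o + 0.05, peak_z=4.0, peak_time=o + 0.02)
            for o in onsets
        ]

    def test_half_open_rule(self):
        events = self._events([10.0, 59.9, 60.0])
        out = swr.window_slice(events, 0.0, 60.0)
        assert len(out) == 2

    def test_rereferencing(self):
        out = swr.window_slice(self._events([70.0]), 60.0, 120.0)
        assert out[0].onset == pytest.approx(10.0)
        assert out[0].peak_time == pytest.approx(10.02)

    def test_empty_and_identity(self):
        assert swr.window_slice([], 0.0, 60.0) == []
        events = self._events([1.0, 2.0])
        assert len(swr.window_slice(events, 0.0, 1e6)) == 2


class TestSummarizeSwr:
    def _events(self, onsets, dur=0.05, immobile=True):
        return [
            SwrEvent(onset=o, offset=o + dur, peak_z=4.0, peak_time=o, immobile=immobile)
            for o in onsets
        ]

    def test_event_frequency_arithmetic(self):
        track = np.zeros(60_000, dtype=bool)
        track[:10_000] = True  # 10 s immobile at 1 kHz
        events = self._events([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        s = swr.summarize_swr(events, track, 1000.0, 60.0)
        assert s.event_frequency == pytest.approx(0.6)

    def test_mean_interval_onset_to_onset(self):
        s = swr.summarize_swr(self._events([1.0, 2.5, 5.0]), None, 1000.0, 60.0)
        assert s.mean_interval_s == pytest.approx(2.0)

    def test_single_event_interval_undefined(self):
        s = swr.summarize_swr(self._events([1.0]), None, 1000.0, 60.0)
        assert np.isnan(s.mean_interval_s)

    def test_baseline_ratio(self):
        base = swr.summarize_swr(self._events([1, 2, 3, 4]), None, 1000.0, 60.0)
        fam = swr.summarize_swr(self._events([1, 2, 3, 4, 5, 6]), None, 1000.0, 60.0)
        assert fam.baseline_ratio == {}
        fam = swr.summarize_swr(
            self._events([1, 2, 3, 4, 5, 6]), None, 1000.0, 60.0, baseline=base
        )
        assert fam.baseline_ratio["count"] == pytest.approx(1.5)

    def test_per_minute_counts_sum_to_total(self):
        events = self._events([0.5, 30.0, 61.0, 130.0, 131.0, 250.0])
        s = swr.summarize_swr(events, None, 1000.0, 300.0)
        assert s.per_minute["count"].sum() == s.count == 6
        assert len(s.per_minute) == 5

    def test_mobile_events_excluded(self):
        events = self._events([1.0, 2.0]) + self._events([3.0], immobile=False)
        s = swr.summarize_swr(events, None, 1000.0, 60.0)
        assert s.count == 2
        s_all = swr.summarize_swr(events, None, 1000.0, 60.0, immobile_only=False)
        assert s_all.count == 3

    def test_zero_immobility_with_events_inconsistent(self):
        track = np.zeros(60_000, dtype=bool)
        with pytest.raises(ValueError, match="immobility"):
            swr.summarize_swr(self._events([1.0]), track, 1000.0, 60.0)

    def test_out_of_range_event_rejected(self):
        with pytest.raises(ValueError, match="trial_duration"):
            swr.summarize_swr(self._events([70.0]), None, 1000.0, 60.0)
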