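"""Tests for the wavelet-based heel-contact detection chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitcx.events import (CwtTrace, HeelContactSeries, chain_to_heel_contacts,
                           cwt_differentiate, detect_heel_contacts,
                           drift_highpass, find_candidate_minima,
                           integrate_velocity, local_maxima, local_minima,
                           relocate_in_raw)
from gaitcx.preprocess import UniformSignal
from gaitcx.synthetic import generate_isi, generate_recording

from conftest import detect_on, match_stats, preprocess_streams


class TestLocalExtrema:
    def test_simple_minima_and_maxima(self):
        x = [3.0, 1.0, 2.0, 0.5, 4.0]
        assert list(local_minima(x)) == [1, 3]
        assert list(local_maxima(x)) == [2]

    def test_plateau_takes_first_sample(self):
        assert list(local_minima([3.0, 1.0, 1.0, 2.0])) == [1]
        assert list(local_maxima([0.0, 2.0, 2.0, 1.0])) == [1]

    def test_monotone_has_no_extrema(self):
        assert local_minima(np.arange(10.0)).size == 0
        assert local_maxima(np.arange(10.0)).size == 0

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_minima_strictly_below_neighbours(self, vals):
        x = np.asarray(vals)
        for i in local_minima(x):
            assert x[i] < x[i - 1]
            nxt = x[i + 1:]
            different = nxt[nxt != x[i]]
            if different.size:
                # the first different value after a (possible) plateau is above
                assert different[0] > x[i]


class TestDriftHighpass:
    def test_preserves_2hz_amplitude(self):
        t = np.arange(0, 60, 0.01)
        sig = UniformSignal(fs=100, a=np.sin(2 * np.pi * 2 * t))
        out = drift_highpass(sig)
        assert np.max(np.abs(out.a[len(out.a) // 2:])) > 0.99

    def test_kills_dc_offset(self):
        sig = UniformSignal(fs=100, a=np.full(30_000, 5.0))
        out = drift_highpass(sig)
        assert abs(out.a[-1]) < 0.01

    def test_attenuates_very_slow_component(self):
        t = np.arange(0, 300, 0.01)
        sig = UniformSignal(fs=100, a=np.sin(2 * np.pi * 0.01 * t))
        out = drift_highpass(sig)
        assert np.max(np.abs(out.a[len(out.a) // 2:])) < 0.1


class TestIntegrateVelocity:
    def test_constant_gives_ramp(self):
        sig = UniformSignal(fs=100, a=np.full(11, 2.0))
        out = integrate_velocity(sig)
        np.testing.assert_allclose(out.a, 2.0 * np.arange(11) * 0.01,
                                   atol=1e-12)

    def test_hand_trapezoid(self):
        sig = UniformSignal(fs=100, a=np.array([0.0, 2.0, 4.0]))
        np.testing.assert_allclose(integrate_velocity(sig).a,
                                   [0.0, 0.01, 0.04], atol=1e-15)

    def test_sine_matches_antiderivative(self):
        f, fs = 1.5, 100.0
        t = np.arange(0, 10, 1 / fs)
        sig = UniformSignal(fs=fs, a=np.sin(2 * np.pi * f * t))
        out = integrate_velocity(sig)
        expected = (1 - np.cos(2 * np.pi * f * t)) / (2 * np.pi * f)
        assert np.max(np.abs(out.a - expected)) < 1e-3  # O(h²) trapezoid error


class TestCwtDifferentiate:
    def test_ramp_gives_constant_slope(self):
        t = np.arange(0, 10, 0.01)
        vel = UniformSignal(fs=100, a=2.5 * t)
        trace = cwt_differentiate(vel)
        mid = trace.c[200:-200]
        np.testing.assert_allclose(mid, 2.5, rtol=1e-6)

    def test_constant_gives_zero(self):
        vel = UniformSignal(fs=100, a=np.full(500, 7.0))
        trace = cwt_differentiate(vel)
        np.testing.assert_allclose(trace.c[100:-100], 0.0, atol=1e-9)

    def test_minima_near_true_contacts(self):
        isi = generate_isi("white", 30, 1.1, 0.0, seed=2)
        rec = generate_recording([isi], timestamp_jitter_sd=0, noise_sd=0,
                                 seed=2)
        sig, sig_f = preprocess_streams(rec.accel)
        vel = integrate_velocity(drift_highpass(sig_f))
        trace = cwt_differentiate(vel)
        cands = find_candidate_minima(trace)
        # one deep trace minimum per stride cycle
        assert cands.size == rec.true_rhc_times.size

    def test_short_signal_raises(self):
        with pytest.raises(ValueError):
            cwt_differentiate(UniformSignal(fs=100, a=np.zeros(50)))


class TestFindCandidateMinima:
    def make_trace(self, minima_vals, spacing_s=1.0, fs=100.0):
        """Triangle-wave trace whose local minima take the given values."""
        gap = int(spacing_s * fs)
        c = np.zeros(gap * (len(minima_vals) + 1))
        for k, v in enumerate(minima_vals):
            c[(k + 1) * gap - gap // 2: (k + 1) * gap + gap // 2] = np.concatenate(
                [np.linspace(0, v, gap // 2, endpoint=False),
                 np.linspace(v, 0, gap // 2, endpoint=False)])
        return CwtTrace(c=c, scale=12, fs=fs)

    def test_ten_equal_minima_all_retained(self):
        trace = self.make_trace([-1.0] * 10)
        # threshold = 0.4 × median(-1 × 10) = -0.4; all pass
        assert find_candidate_minima(trace).size == 10

    def test_weak_minima_rejected_by_threshold(self):
        trace = self.make_trace([-1.0] * 10 + [-0.3] * 5)
        assert find_candidate_minima(trace).size == 10

    def test_separation_keeps_more_negative(self):
        trace = self.make_trace([-1.0] * 10)
        # add a conflicting pair 0.5 s apart: -1.0 then -0.8
        extra = self.make_trace([-1.0, -0.8], spacing_s=0.5)
        c = np.concatenate([trace.c, extra.c, trace.c])
        out = find_candidate_minima(CwtTrace(c=c, scale=12, fs=100))
        vals = c[out]
        assert -0.8 not in vals and np.sum(np.isclose(vals, -1.0)) == 21

    def test_too_few_minima_raises(self):
        with pytest.raises(ValueError):
            find_candidate_minima(self.make_trace([-1.0] * 5))


class TestChainAndRelocate:
    def test_clean_synthetic_thirty_strides(self, clean_recording):
        ev_f, ev_r = detect_on(clean_recording.accel)
        truth = clean_recording.true_rhc_times
        assert ev_r.n_events == truth.size == 31
        recall, precision = match_stats(ev_r.times, truth)
        assert recall == 1.0 and precision == 1.0

    def test_candidate_near_end_dropped(self):
        # rising trace after the last candidate -> no maximum to chain to
        c = np.zeros(3000)
        for k in range(10):
            c[200 + k * 250] = -1.0
            c[201 + k * 250: 230 + k * 250] = 0.5  # max after each minimum
        c[2900] = -1.0  # candidate with no subsequent maximum
        trace = CwtTrace(c=c, scale=12, fs=100)
        sig = UniformSignal(fs=100, a=np.sin(np.arange(3000) / 5),
                            stream="filtered")
        cands = find_candidate_minima(trace)
        out = chain_to_heel_contacts(sig, trace, cands)
        assert 2900 not in out.indices
        assert out.n_events <= cands.size

    def test_relocate_identity_when_raw_equals_filtered(self, clean_recording):
        sig, sig_f = preprocess_streams(clean_recording.accel)
        ev_f, _ = detect_heel_contacts(sig, sig_f)
        same = relocate_in_raw(ev_f, sig_f)
        np.testing.assert_array_equal(same.indices, ev_f.indices)
        assert same.stream == "raw"

    def test_relocate_finds_shifted_minimum(self):
        # raw minimum sits 2 frames after the filtered one
        filt = np.zeros(2000)
        raw = np.zeros(2000)
        idx = np.arange(100, 2000, 100)
        for i in idx:
            filt[i - 3:i + 4] = [3, 1, -1, -2, -1, 1, 3]
            raw[i - 1:i + 6] = [3, 1, -1, -2, -1, 1, 3]
        ev = HeelContactSeries(indices=idx, stream="filtered", fs=100)
        sig_raw = UniformSignal(fs=100, a=raw)
        out = relocate_in_raw(ev, sig_raw, offset_frames=3)
        np.testing.assert_array_equal(out.indices, idx + 2)

    def test_event_count_preserved_on_clean_input(self, clean_recording):
        ev_f, ev_r = detect_on(clean_recording.accel)
        assert ev_r.n_events == ev_f.n_events


class TestDetectionInvariants:
    @pytest.mark.parametrize("stride_s", [0.9, 1.0, 1.15, 1.25, 1.4])
    def test_perfect_detection_across_stride_times(self, stride_s):
        isi = generate_isi("white", 35, stride_s, 0.0, seed=0)
        rec = generate_recording([isi], timestamp_jitter_sd=0, noise_sd=0,
                                 seed=0)
        _, ev_r = detect_on(rec.accel)
        recall, precision = match_stats(ev_r.times, rec.true_rhc_times)
        assert recall == 1.0 and precision == 1.0

    def test_spacing_invariant_above_separation(self):
        isi = generate_isi("fgn", 60, 1.12, 0.04, 0.9, seed=5)
        rec = generate_recording([isi], noise_sd=0.5, seed=5)
        ev_f, ev_r = detect_on(rec.accel)
        for ev in (ev_f, ev_r):
            assert np.all(np.diff(ev.times) > 0.8)

    def test_invariant_to_positive_rescaling(self, clean_recording):
        sig, sig_f = preprocess_streams(clean_recording.accel)
        _, ev1 = detect_heel_contacts(sig, sig_f)
        sig2 = UniformSignal(fs=sig.fs, a=sig.a * 7.3, stream="raw",
                             t0=sig.t0)
        sig2_f = UniformSignal(fs=sig_f.fs, a=sig_f.a * 7.3,
                               stream="filtered", t0=sig_f.t0)
        _, ev2 = detect_heel_contacts(sig2, sig2_f)
        np.testing.assert_array_equal(ev1.indices, ev2.indices)

    def test_detection_does_not_mutate_inputs(self, clean_recording):
        sig, sig_f = preprocess_streams(clean_recording.accel)
        before = (sig.a.copy(), sig_f.a.copy())
        detect_heel_contacts(sig, sig_f)
        np.testing.assert_array_equal(sig.a, before[0])
        np.testing.assert_array_equal(sig_f.a, before[1])
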