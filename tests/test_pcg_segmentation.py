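"""Envelope segmentation of the PCG: filtering, entropy, gate, boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgfusion import (
    EnvelopeTrace,
    GateSignal,
    InputError,
    ParameterError,
    SignalTrace,
    adaptive_threshold,
    bandpass_pcg,
    extract_boundaries,
    gate_envelope,
    match_detections,
    segment_pcg,
    shannon_envelope,
    smooth_envelope,
)
from pcgfusion.fusion_classifier import LabeledSound
from pcgfusion.synth import SynthConfig, generate_recording


def naive_shannon_envelope(x, window_n):
    """Independent double-loop reference for the entropy envelope."""
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        lo = max(0, i - window_n // 2)
        hi = min(n, i + (window_n - 1) // 2 + 1)
        acc = 0.0
        for j in range(lo, hi):
            y = abs(x[j]) ** 3
            if y > 0:
                acc += -y * np.log(y)
        out[i] = acc / (hi - lo)
    return out


def _sine(freq, fs, dur=1.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return SignalTrace(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestBandpass:
    def test_dc_rejected(self):
        """A baseline offset contributes nothing to the filtered output."""
        tr = _sine(100, 1000.0)
        shifted = SignalTrace(samples=tr.samples + 1.0, fs=tr.fs)
        base = bandpass_pcg(tr, 20, 200)
        out = bandpass_pcg(shifted, 20, 200)
        assert np.max(np.abs(out.samples - base.samples)) < 1e-9
        flat = bandpass_pcg(SignalTrace(samples=np.full(1000, 1.0), fs=1000.0), 20, 200)
        assert np.mean(np.abs(flat.samples)) < 1e-3

    def test_passband_tone_survives(self):
        out = bandpass_pcg(_sine(100, 1000.0), 20, 200)
        amp = np.max(np.abs(out.samples[200:-200]))
        assert amp > 0.95

    def test_stopband_tone_attenuated(self):
        out = bandpass_pcg(_sine(500, 2000.0), 20, 200)
        amp = np.max(np.abs(out.samples[200:-200]))
        assert amp < 0.05

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_pcg(_sine(100, 1000.0), 20, 600)


class TestAdaptiveThreshold:
    def test_all_zero_unchanged(self):
        tr = SignalTrace(samples=np.zeros(10), fs=1000.0)
        assert np.array_equal(adaptive_threshold(tr).samples, np.zeros(10))

    def test_hand_example(self):
        tr = SignalTrace(samples=np.array([0.5, -2.0, 0.01]), fs=1000.0)
        out = adaptive_threshold(tr, floor_frac=0.1)
        assert np.allclose(out.samples, [0.25, -1.0, 0.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50))
    @settings(deadline=None)
    def test_output_max_is_zero_or_one(self, values):
        tr = SignalTrace(samples=np.asarray(values), fs=1000.0)
        peak = np.max(np.abs(adaptive_threshold(tr).samples))
        assert peak == 0.0 or peak == pytest.approx(1.0)


class TestShannonEnvelope:
    def test_zero_input_zero_envelope(self):
        tr = SignalTrace(samples=np.zeros(100), fs=1000.0)
        assert np.all(shannon_envelope(tr, 20).values == 0.0)

    def test_constant_one_gives_zero(self):
        tr = SignalTrace(samples=np.ones(100), fs=1000.0)
        assert np.allclose(shannon_envelope(tr, 20).values, 0.0)

    def test_constant_half_analytic_value(self):
        # |0.5^3| = 0.125; -0.125*ln(0.125) = 0.259930...
        tr = SignalTrace(samples=np.full(100, 0.5), fs=1000.0)
        expected = -0.125 * np.log(0.125)
        assert np.allclose(shannon_envelope(tr, 20).values, expected)
        assert expected == pytest.approx(0.259930, abs=1e-6)

    def test_amplitude_above_one_rejected(self):
        tr = SignalTrace(samples=np.array([0.0, 1.5, 0.0]), fs=1000.0)
        with pytest.raises(InputError):
            shannon_envelope(tr, 5)

    def test_matches_naive_double_loop(self, rng):
        for window_n in (1, 7, 20):
            x = rng.uniform(-1, 1, size=500)
            tr = SignalTrace(samples=x, fs=1000.0)
            fast = shannon_envelope(tr, window_n).values
            assert np.max(np.abs(fast - naive_shannon_envelope(x, window_n))) < 1e-12

    def test_nonnegative_for_normalized_input(self, rng):
        x = rng.uniform(-1, 1, size=2000)
        env = shannon_envelope(SignalTrace(samples=x, fs=1000.0), 20)
        assert np.all(env.values >= 0.0)

    def test_locality_of_window(self, rng):
        """Perturbing a sample outside the window leaves SE unchanged there."""
        x = rng.uniform(-0.9, 0.9, size=200)
        tr = SignalTrace(samples=x, fs=1000.0)
        base = shannon_envelope(tr, 20).values
        y = x.copy()
        y[150] = 0.0  # far from position 50 (window spans +-10 samples)
        pert = shannon_envelope(SignalTrace(samples=y, fs=1000.0), 20).values
        assert base[50] == pert[50]
        assert base[150] != pert[150]


class TestSmoothEnvelope:
    def _env(self, values, fs=1000.0):
        return EnvelopeTrace(values=np.asarray(values, float), fs=fs, window_n=20)

    def test_constant_unchanged(self):
        env = self._env(np.full(100, 0.7))
        assert np.allclose(smooth_envelope(env, 0.01).values, 0.7)

    def test_symmetric_peak_keeps_argmax(self):
        tri = np.concatenate([np.arange(50.0), np.arange(50.0)[::-1]])
        out = smooth_envelope(self._env(tri), 0.015)
        assert abs(int(np.argmax(out.values)) - 49) <= 1

    def test_impulse_double_pass_response(self):
        """3-tap mean applied twice: symmetric 5-tap response summing to 1."""
        imp = np.zeros(101)
        imp[50] = 1.0
        out = smooth_envelope(self._env(imp), 0.003).values
        resp = out[48:53]
        assert np.allclose(resp, [1 / 9, 2 / 9, 3 / 9, 2 / 9, 1 / 9])
        assert out.sum() == pytest.approx(1.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ParameterError):
            smooth_envelope(self._env(np.ones(10)), 1.0)


class TestGateEnvelope:
    def _env(self, values):
        return EnvelopeTrace(values=np.asarray(values, float), fs=1000.0, window_n=20)

    def test_constant_envelope_all_zero(self):
        gate = gate_envelope(self._env(np.full(50, 0.3)), offset=0.01)
        assert np.all(gate.values == 0)

    def test_hand_example_threshold(self):
        gate = gate_envelope(self._env([0, 0, 1, 1, 0, 0]), offset=0.01)
        assert gate.threshold == pytest.approx(1 / 3 + 0.01)
        assert list(gate.values) == [0, 0, 1, 1, 0, 0]

    def test_scale_invariance_at_zero_offset(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 1, size=100)
            g1 = gate_envelope(self._env(v), offset=0.0).values
            g2 = gate_envelope(self._env(10 * v), offset=0.0).values
            assert np.array_equal(g1, g2)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    @settings(deadline=None)
    def test_edge_conservation(self, values):
        """Rising and falling edges balance after end-closure."""
        gate = gate_envelope(self._env(values), offset=0.01)
        v = np.concatenate(([0], gate.values, [0]))
        d = np.diff(v)
        assert np.sum(d == 1) == np.sum(d == -1)


class TestExtractBoundaries:
    def _gate(self, bits, fs=1000.0):
        return GateSignal(values=np.asarray(bits), fs=fs, threshold=0.0)

    def test_all_zero_gate_empty(self):
        assert extract_boundaries(self._gate([0] * 10)) == []

    def test_hand_traced_edges(self):
        gate = self._gate([0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 0])
        bounds = extract_boundaries(gate, min_dur_s=0.001, max_dur_s=1.0, merge_gap_s=0.0)
        assert [(b.start_s, b.end_s) for b in bounds] == [
            (pytest.approx(0.002), pytest.approx(0.005)),
            (pytest.approx(0.008), pytest.approx(0.010)),
        ]

    def test_gap_merging(self):
        # two 40 ms segments separated by a 10 ms gap -> one 90 ms sound
        bits = [0] * 10 + [1] * 40 + [0] * 10 + [1] * 40 + [0] * 10
        bounds = extract_boundaries(
            self._gate(bits), min_dur_s=0.001, max_dur_s=1.0, merge_gap_s=0.020
        )
        assert len(bounds) == 1
        assert bounds[0].duration_s == pytest.approx(0.090)

    def test_duration_limits_discard(self):
        bits = [0] * 5 + [1] * 10 + [0] * 50 + [1] * 300 + [0] * 5
        bounds = extract_boundaries(
            self._gate(bits), min_dur_s=0.030, max_dur_s=0.250, merge_gap_s=0.0
        )
        assert bounds == []

    def test_open_segment_closed_at_end(self):
        bits = [0] * 5 + [1] * 50
        bounds = extract_boundaries(
            self._gate(bits), min_dur_s=0.030, max_dur_s=0.250, merge_gap_s=0.0
        )
        assert len(bounds) == 1
        assert bounds[0].end_s == pytest.approx(54 / 1000)

    def test_boundaries_sorted_disjoint(self, rng):
        bits = (rng.uniform(size=3000) > 0.5).astype(int)
        bounds = extract_boundaries(
            self._gate(bits), min_dur_s=0.0, max_dur_s=10.0, merge_gap_s=0.003
        )
        for a, b in zip(bounds, bounds[1:]):
            assert a.end_s < b.start_s


class TestSegmentPcg:
    def test_silence_gives_no_sounds(self):
        tr = SignalTrace(samples=np.zeros(10_000), fs=1000.0)
        assert segment_pcg(tr) == []

    def test_noiseless_recording_start_points(self, clean_recording):
        """Every true S1/S2 onset is recovered within +-10 ms, one-to-one."""
        rec = clean_recording
        bounds = segment_pcg(rec.pcg)
        assert len(bounds) == 2 * rec.n_cycles
        det = [LabeledSound(start_s=b.start_s, label="S1") for b in bounds]
        rep = match_detections(det, rec.truth_s1, rec.truth_s2, tol_s=0.010)
        assert rep.fn == 0 and rep.fp == 0

    def test_noisy_recording_sensitivity(self, noisy_recording):
        rec = noisy_recording
        det = [
            LabeledSound(start_s=b.start_s, label="S1") for b in segment_pcg(rec.pcg)
        ]
        rep = match_detections(det, rec.truth_s1, rec.truth_s2, tol_s=0.010)
        assert rep.sensitivity >= 0.95

    def test_sensitivity_non_increasing_with_noise(self):
        """Detection can only degrade as additive noise grows."""
        sens = []
        for snr in (30.0, 20.0, 10.0, 0.0):
            rec = generate_recording(SynthConfig(seed=7, duration_s=30.0, snr_db=snr))
            det = [
                LabeledSound(start_s=b.start_s, label="S1")
                for b in segment_pcg(rec.pcg)
            ]
            rep = match_detections(det, rec.truth_s1, rec.truth_s2, tol_s=0.010)
            sens.append(rep.sensitivity)
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
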