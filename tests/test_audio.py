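"""Stimulus-level audio processing: energy, ramps, features, scrambling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpas.audio import (SilentStimulusError, Waveform, apply_ramps,
                        estimate_pitch, hilbert_envelope, hnr, read_wav,
                        rms_equalize, scramble_frequency, spectral_cog,
                        synthesize_vocalization, write_wav)
from fpas.audio import _scramble_spectrum

from conftest import RATE, harmonic_complex


def sine(freq, rate=RATE, dur=0.35, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


class TestRmsEqualize:
    def test_sine_closed_form(self):
        w = sine(440.0)
        out = rms_equalize(w, 0.1)
        assert out.rms == pytest.approx(0.1, rel=1e-9)
        scale = out.samples[100] / w.samples[100]
        assert scale == pytest.approx(0.1 / (1 / np.sqrt(2)), rel=1e-3)

    def test_identity_when_at_target(self):
        w = sine(440.0)
        target = w.rms
        out = rms_equalize(w, target)
        assert np.array_equal(out.samples, w.samples)

    def test_seeded_noise_remeasured(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.uniform(-1, 1, 4000), RATE)
        out = rms_equalize(w, 0.05)
        assert np.sqrt(np.mean(out.samples**2)) == pytest.approx(0.05,
                                                                 rel=1e-9)

    def test_silent_input_raises(self):
        with pytest.raises(SilentStimulusError):
            rms_equalize(Waveform(np.zeros(100), RATE), 0.1)

    @given(st.floats(0.01, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, target):
        w = sine(200.0)
        once = rms_equalize(w, target)
        twice = rms_equalize(once, target)
        assert np.allclose(once.samples, twice.samples)


class TestApplyRamps:
    def test_envelope_endpoints(self):
        w = Waveform(np.ones(1000), 1000)  # 1 s at 1 kHz
        out = apply_ramps(w, ramp_ms=10)
        assert out.samples[0] == 0.0
        assert np.all(out.samples[10:-10] == 1.0)

    def test_zero_ramp_is_identity(self):
        w = sine(100.0)
        assert np.array_equal(apply_ramps(w, 0).samples, w.samples)

    def test_energy_strictly_reduced(self):
        w = sine(100.0)
        assert np.sum(apply_ramps(w).samples**2) < np.sum(w.samples**2)

    def test_too_long_ramp_raises(self):
        with pytest.raises(ValueError):
            apply_ramps(sine(100.0, dur=0.015), ramp_ms=10)


class TestSpectralCog:
    def test_pure_tone(self):
        assert spectral_cog(sine(440.0)) == pytest.approx(440.0, abs=1.0)

    def test_equal_power_pair_symmetry(self):
        t = np.arange(int(0.35 * RATE)) / RATE
        w = Waveform(np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t),
                     RATE)
        assert spectral_cog(w) == pytest.approx(200.0, abs=1.0)

    def test_white_noise_half_nyquist(self):
        rng = np.random.default_rng(1)
        w = Waveform(rng.standard_normal(80000), 8000)
        assert spectral_cog(w) == pytest.approx(2000.0, rel=0.05)

    def test_silent_raises(self):
        with pytest.raises(SilentStimulusError):
            spectral_cog(Waveform(np.zeros(100), RATE))


class TestPitchAndHnr:
    def test_sawtooth_f0(self):
        t = np.arange(int(0.35 * RATE)) / RATE
        saw = Waveform(2 * ((200.0 * t) % 1.0) - 1.0, RATE)
        assert estimate_pitch(saw) == pytest.approx(200.0, abs=2.0)

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(2)
        w = Waveform(rng.standard_normal(int(0.35 * RATE)), RATE)
        assert estimate_pitch(w) is None
        assert hnr(w) is None

    def test_harmonic_complex_f0(self):
        assert estimate_pitch(harmonic_complex(150.0)) == pytest.approx(
            150.0, abs=2.0)

    def test_pure_sine_hits_cap(self):
        assert hnr(sine(200.0)) == pytest.approx(60.0)

    @pytest.mark.parametrize("power_ratio,expected", [(1.0, 0.0), (10.0, 10.0)])
    def test_sine_plus_noise(self, power_ratio, expected):
        # HNR = 10 log10(P_harmonic / P_noise)
        rng = np.random.default_rng(3)
        t = np.arange(int(2.0 * RATE)) / RATE
        s = np.sqrt(2) * np.sin(2 * np.pi * 200 * t)      # power 1
        n = rng.standard_normal(len(t)) / np.sqrt(power_ratio)
        w = Waveform(s + n, RATE)
        assert hnr(w, require_voiced=False) == pytest.approx(expected,
                                                             abs=1.0)


class TestHilbertEnvelope:
    def test_am_tone_recovers_modulator(self):
        t = np.arange(int(0.35 * RATE)) / RATE
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 8 * t)
        w = Waveform(a * np.cos(2 * np.pi * 1000 * t), RATE)
        env = hilbert_envelope(w).samples
        mid = slice(200, -200)
        assert np.max(np.abs(env[mid] - a[mid])) < 0.05 * a.max()

    def test_constant_sine(self):
        env = hilbert_envelope(sine(1000.0)).samples
        assert np.allclose(env[200:-200], 1.0, atol=0.02)

    def test_zero_input(self):
        env = hilbert_envelope(Waveform(np.zeros(500), RATE)).samples
        assert np.all(env == 0.0)


class TestScramble:
    def test_magnitude_multiset_preserved_per_window(self):
        w = harmonic_complex(173.0, 10)
        spec = np.fft.rfft(w.samples)
        rng = np.random.default_rng(5)
        out = _scramble_spectrum(spec, len(w.samples), w.rate, 200.0, rng,
                                 "joint")
        n_per_win = int(round(200.0 / (w.rate / len(w.samples))))
        stop = len(spec) - 1 if len(w.samples) % 2 == 0 else len(spec)
        for start in range(1, stop, n_per_win):
            idx = np.arange(start, min(start + n_per_win, stop))
            assert np.allclose(np.sort(np.abs(spec[idx])),
                               np.sort(np.abs(out[idx])))
        assert out[0] == spec[0]        # DC untouched

    def test_determinism_contract(self):
        w = harmonic_complex()
        a = scramble_frequency(w, seed=9)
        b = scramble_frequency(w, seed=9)
        c = scramble_frequency(w, seed=10)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_duration_rate_rms_preserved(self):
        w = harmonic_complex()
        s = scramble_frequency(w, seed=4)
        assert len(s.samples) == len(w.samples)
        assert s.rate == w.rate
        # RMS equalization happens before ramping, so compare pre-ramp level
        assert s.rms == pytest.approx(w.rms, rel=0.05)

    def test_window_narrower_than_bin_raises(self):
        w = harmonic_complex()
        with pytest.raises(ValueError):
            scramble_frequency(w, window_hz=1.0, seed=0)

    def test_envelope_correlation_preserved(self, stimulus_set):
        # smoothed (20 Hz) temporal envelopes of scrambled vocalizations
        # track the originals
        rs = []
        for i, key in enumerate(sorted(stimulus_set.sounds)[:20]):
            w = stimulus_set.sounds[key]
            s = scramble_frequency(w, seed=1000 + i)
            eo = hilbert_envelope(w, smooth_hz=20.0).samples
            es = hilbert_envelope(s, smooth_hz=20.0).samples
            rs.append(np.corrcoef(eo, es)[0, 1])
        # multiply-mode reapplication leaves random carrier ripple, so
        # individual stimuli scatter; the set-level correlation is high
        assert np.mean(rs) > 0.8
        assert min(rs) > 0.5

    def test_cog_preserved_on_harmonic_complexes(self):
        for i, f0 in enumerate((120.0, 180.0, 240.0)):
            w = harmonic_complex(f0, 8)
            s = scramble_frequency(w, seed=50 + i)
            assert spectral_cog(s) / spectral_cog(w) == pytest.approx(
                1.0, abs=0.10)

    def test_harmonicity_disrupted(self, stimulus_set):
        for i, key in enumerate(sorted(stimulus_set.sounds)[:10]):
            w = stimulus_set.sounds[key]
            s = scramble_frequency(w, seed=2000 + i)
            assert hnr(s, require_voiced=False) < hnr(w, require_voiced=False)

    def test_independent_mode_differs_from_joint(self):
        w = harmonic_complex()
        a = scramble_frequency(w, seed=6, mode="joint")
        b = scramble_frequency(w, seed=6, mode="independent")
        assert not np.array_equal(a.samples, b.samples)

    def test_impose_mode_envelope_nearly_exact(self):
        w = synthesize_vocalization("fear", 77)
        s = scramble_frequency(w, seed=8, envelope_mode="impose")
        eo = hilbert_envelope(w, smooth_hz=20.0).samples
        es = hilbert_envelope(s, smooth_hz=20.0).samples
        assert np.corrcoef(eo, es)[0, 1] > 0.95


class TestSyntheticVocalizations:
    def test_contract(self):
        w = synthesize_vocalization("anger", 3)
        assert w.duration == pytest.approx(0.350)
        # ramps follow equalization, trimming a sliver of energy
        assert w.rms == pytest.approx(0.1, rel=0.02)
        assert w.category == "anger"

    def test_voiced_and_in_pitch_range(self):
        pitches = [estimate_pitch(synthesize_vocalization("sadness", s))
                   for s in range(5)]
        assert all(p is not None and 75 <= p <= 600 for p in pitches)

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError):
            synthesize_vocalization("surprise", 0)


class TestWavIO:
    @pytest.mark.parametrize("subtype", ["float32", "pcm16"])
    def test_roundtrip(self, tmp_path, subtype):
        w = synthesize_vocalization("happiness", 11)
        path = tmp_path / "stim.wav"
        write_wav(path, w, subtype=subtype)
        back = read_wav(path)
        assert back.rate == w.rate
        tol = 1e-6 if subtype == "float32" else 1e-3
        scale = 1.0 if subtype == "float32" \
            else np.dot(back.samples, w.samples) / np.dot(w.samples,
                                                          w.samples)
        assert np.allclose(back.samples, scale * w.samples, atol=tol)
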