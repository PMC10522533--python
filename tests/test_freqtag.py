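"""Preprocessing and frequency-domain harmonic statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fpas.freqtag import (AmplitudeSpectrumSet, NoisePolicy,
                          amplitude_spectrum, bh_fdr, chunk_sum_z,
                          contrast_intact_scrambled, crop_and_average,
                          harmonic_bin_indices, harmonic_z,
                          interpolate_channels, leading_significant_run,
                          nearest_neighbors, noise_stats, paired_onetailed_t,
                          per_participant_response, preprocess, quantify,
                          rereference, segment_trials, select_harmonics)
from fpas.io import EEGRecording, biosemi128_layout


def sine_rec(freq, rate=512, dur=10.0, n_ch=4, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return EEGRecording(data, rate, [f"ch{i}" for i in range(n_ch)])


def flat_spectrum(value=1.0, n_ch=2, n_bins=400, df=1 / 52.8):
    return AmplitudeSpectrumSet(np.full((n_ch, n_bins), value), df,
                                n_bins * df)


class TestPreprocess:
    # the 0.1 Hz high-pass settles over ~10 s, so steady-state behavior
    # is measured on the central third of a 60 s signal
    def test_notch_attenuates_line_noise(self):
        rec = sine_rec(50.0, dur=60.0, n_ch=1)
        out = preprocess(rec)
        mid = slice(out.n_samples // 3, -out.n_samples // 3)
        atten = np.max(np.abs(out.data[0, mid]))
        assert atten < 10 ** (-20 / 20)           # > 20 dB down

    def test_passband_amplitude_and_phase(self):
        rec = sine_rec(10.0, dur=60.0, n_ch=1)
        out = preprocess(rec)
        t = np.arange(out.n_samples) / out.rate
        ref = np.sin(2 * np.pi * 10.0 * t)
        mid = slice(out.n_samples // 3, -out.n_samples // 3)
        # zero-phase contract: the filtered 10 Hz sine stays aligned
        assert np.max(np.abs(out.data[0, mid])) == pytest.approx(1.0,
                                                                 rel=0.05)
        assert np.corrcoef(out.data[0, mid], ref[mid])[0, 1] > 0.999

    def test_resampling_contract(self):
        rec = sine_rec(10.0)
        out = preprocess(rec)
        assert out.rate == 256
        assert abs(out.n_samples - rec.n_samples / 2) <= 1

    def test_rate_mismatch_raises(self):
        with pytest.raises(ValueError):
            preprocess(sine_rec(10.0, rate=256))


class TestSegmentTrials:
    def test_trial_length(self):
        rate = 256
        rec = EEGRecording(np.zeros((2, rate * 70)), rate, ["a", "b"],
                           events=[(round(2.5 * rate), 1)])
        trials = segment_trials(rec)
        assert len(trials) == 1
        assert trials[0].n_samples == 15770       # round(61.6 * 256)

    def test_no_events(self):
        rec = EEGRecording(np.zeros((1, 100)), 256, ["a"])
        assert segment_trials(rec) == []

    def test_out_of_bounds_names_event(self):
        rec = EEGRecording(np.zeros((1, 1000)), 256, ["a"],
                           events=[(10, 7)])
        with pytest.raises(ValueError, match="code 7"):
            segment_trials(rec)


class TestInterpolation:
    def test_identical_neighbors_replacement(self):
        names, positions = biosemi128_layout()
        rng = np.random.default_rng(0)
        data = rng.normal(size=(130, 100))
        rec = EEGRecording(data, 512, names, positions)
        bad = names[40]
        good = np.array([i for i in range(130) if i != 40])
        nn = nearest_neighbors(positions, 40, good, 3)
        rec.data[nn] = rec.data[nn[0]]           # all three identical
        out = interpolate_channels(rec, [bad])
        assert np.allclose(out.data[40], rec.data[nn[0]])

    def test_idempotent(self):
        names, positions = biosemi128_layout()
        rng = np.random.default_rng(1)
        rec = EEGRecording(rng.normal(size=(130, 50)), 512, names, positions)
        once = interpolate_channels(rec, [names[7]])
        twice = interpolate_channels(once, [names[7]])
        assert np.allclose(once.data, twice.data)

    def test_neighbor_selection_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pos = rng.normal(size=(30, 3))
            target = int(rng.integers(30))
            cand = np.array([i for i in range(30) if i != target])
            got = nearest_neighbors(pos, target, cand, 3)
            dists = {i: np.linalg.norm(pos[i] - pos[target]) for i in cand}
            expect = sorted(cand, key=lambda i: dists[i])[:3]
            assert sorted(dists[i] for i in got) == pytest.approx(
                sorted(dists[i] for i in expect))

    def test_unknown_channel(self):
        names, positions = biosemi128_layout()
        rec = EEGRecording(np.zeros((130, 10)), 512, names, positions)
        with pytest.raises(ValueError, match="unknown"):
            interpolate_channels(rec, ["Zz9"])


class TestRereference:
    @pytest.fixture()
    def rec(self):
        names, positions = biosemi128_layout()
        rng = np.random.default_rng(3)
        return EEGRecording(rng.normal(5.0, 10.0, (130, 64)), 512, names,
                            positions)

    def test_average_reference_zero_mean(self, rec):
        out = rereference(rec, "average")
        scalp_mean = out.data[out.scalp_picks()].mean(axis=0)
        assert np.max(np.abs(scalp_mean)) < 1e-9

    def test_idempotent(self, rec):
        once = rereference(rec, "average")
        assert np.allclose(rereference(once, "average").data, once.data)

    def test_constant_offset_removed(self, rec):
        shifted = rec.copy()
        shifted.data = rec.data + 42.0
        assert np.allclose(rereference(shifted, "average").data,
                           rereference(rec, "average").data)

    def test_linked_mastoids(self, rec):
        out = rereference(rec, "linked_mastoids")
        m = out.data[out.mastoid_picks()].mean(axis=0)
        assert np.max(np.abs(m)) < 1e-9

    def test_missing_mastoids(self):
        rec = EEGRecording(np.zeros((3, 10)), 512, ["a", "b", "c"])
        with pytest.raises(ValueError):
            rereference(rec, "linked_mastoids")


class TestCropAndAverage:
    def test_integer_cycle_arithmetic(self):
        assert 52.8 * (2.5 / 3) == pytest.approx(44.0)
        assert 52.8 * 2.5 == pytest.approx(132.0)

    def test_identical_trials_identity(self):
        rate = 256
        rng = np.random.default_rng(4)
        data = rng.normal(size=(2, round(61.6 * rate)))
        trial = EEGRecording(data, rate, ["a", "b"],
                             events=[(round(2 * rate), 1)])
        avg = crop_and_average([trial] * 5)
        single = crop_and_average([trial])
        assert np.allclose(avg.data, single.data)
        assert avg.n_samples == round(52.8 * rate)

    def test_noise_reduction_sqrt_n(self):
        rate = 256
        rng = np.random.default_rng(5)
        sds = []
        for n in (1, 16):
            trials = [EEGRecording(rng.normal(size=(1, round(61.6 * rate))),
                                   rate, ["a"], events=[(round(2 * rate), 1)])
                      for _ in range(n)]
            sds.append(crop_and_average(trials).data.std())
        assert sds[0] / sds[1] == pytest.approx(4.0, rel=0.15)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            crop_and_average([])


class TestAmplitudeSpectrum:
    def test_bin_centered_sinusoid_reads_its_amplitude(self):
        rate, n = 256, round(52.8 * 256)
        df = rate / n
        freq = 44 * df                       # target-rate bin
        t = np.arange(n) / rate
        rec = EEGRecording(np.sin(2 * np.pi * freq * t)[None, :], rate,
                           ["a"])
        spec = amplitude_spectrum(rec)
        assert spec.amps[0, 44] == pytest.approx(1.0, abs=1e-6)
        assert np.max(spec.amps[0, [43, 45]]) < 1e-6

    def test_frequency_resolution(self):
        rec = EEGRecording(np.zeros((1, round(52.8 * 256))), 256, ["a"])
        spec = amplitude_spectrum(rec)
        assert round(spec.df, 4) == 0.0189

    def test_parseval(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 4096))
        rec = EEGRecording(x, 256, ["a"])
        spec = amplitude_spectrum(rec)
        # undo single-sided scaling: power = sum A_k^2 / 2 (+ DC term)
        power = spec.amps[0, 0] ** 2 + np.sum(spec.amps[0, 1:-1] ** 2) / 2 \
            + spec.amps[0, -1] ** 2
        assert power == pytest.approx(np.mean(x**2), rel=1e-9)


class TestHarmonicBins:
    def test_fear_harmonic_list_matches_design(self):
        df = 1 / 52.8
        bins = harmonic_bin_indices(2.5 / 3, df, fmax=6.0, exclude_base=2.5)
        freqs = bins * df
        assert list(bins) == [44, 88, 176, 220, 308]
        assert np.allclose(freqs, [0.833, 1.667, 3.333, 4.167, 5.833],
                           atol=5e-3)
        assert len(bins) == 5

    def test_base_harmonics_not_excluded_for_base_analysis(self):
        bins = harmonic_bin_indices(2.5, 1 / 52.8, fmax=8.0)
        assert list(bins) == [132, 264, 396]


class TestNoiseStats:
    def test_flat_spectrum(self):
        spec = flat_spectrum(3.0)
        mu, sd = noise_stats(spec.amps, 100)
        assert np.allclose(mu, 3.0)
        assert np.allclose(sd, 0.0)

    def test_outlier_removed_by_drop_extremes(self):
        amps = np.full((1, 200), 2.0)
        amps[0, 95] = 50.0                      # outlier inside the window
        mu_out, _ = noise_stats(amps, 100)
        amps2 = np.full((1, 200), 2.0)
        mu_ref, _ = noise_stats(amps2, 100)
        assert mu_out == pytest.approx(mu_ref)

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        policy = NoisePolicy()
        for _ in range(500):
            spec = rng.uniform(0.1, 2.0, size=300)
            b = int(rng.integers(14, 286))
            mu, sd = noise_stats(spec, b, policy)
            offsets = [o for o in range(-13, 14)
                       if abs(o) >= 2]
            window = sorted(spec[b + o] for o in offsets)[1:-1]
            assert mu == pytest.approx(np.mean(window))
            assert sd == pytest.approx(np.std(window, ddof=1))
            assert len(window) == 22

    def test_edge_bin_raises(self):
        with pytest.raises(ValueError):
            noise_stats(np.ones((1, 100)), 5)


class TestHarmonicZ:
    def test_definitional_z(self):
        rng = np.random.default_rng(8)
        amps = rng.uniform(0.9, 1.1, size=(1, 400))
        spec = AmplitudeSpectrumSet(amps, 1 / 52.8, 400 / 52.8)
        bins, _ = harmonic_z(spec, 2.5 / 3, fmax=2.0)
        b = bins[0]
        mu, sd = noise_stats(spec.pooled(), b)
        amps[0, b] = mu + 2.32 * sd
        _, z = harmonic_z(spec, 2.5 / 3, fmax=2.0)
        assert z[0] == pytest.approx(2.32)

    def test_zero_sigma_convention(self):
        spec = flat_spectrum(1.0)
        spec.amps[:, 44] = 2.0
        _, z = harmonic_z(spec, 2.5 / 3, fmax=1.0)
        assert np.isinf(z[0])
        spec.amps[:, 44] = 1.0
        _, z = harmonic_z(spec, 2.5 / 3, fmax=1.0)
        assert z[0] == 0.0


class TestSelectHarmonics:
    def test_rule_application(self):
        bins = np.arange(5)
        z_i = np.array([5, 4, 3, 3, 1])
        z_s = np.array([3, 1, 0, 0, 0])
        assert list(select_harmonics(bins, z_i, z_s)) == [0, 1, 2, 3]

    def test_empty_selection_flagged(self):
        bins = np.arange(3)
        z = np.array([1.0, 0.5, 0.2])
        sel = select_harmonics(bins, z, z)
        assert len(sel) == 0

    def test_scrambled_longer_run_wins(self):
        bins = np.arange(4)
        z_i = np.array([3.0, 1.0, 0.0, 0.0])
        z_s = np.array([4.0, 3.0, 2.9, 1.0])
        assert list(select_harmonics(bins, z_i, z_s)) == [0, 1, 2]

    def test_leading_run_only(self):
        assert leading_significant_run(np.array([1.0, 5.0, 5.0])) == 0


class TestQuantify:
    def test_flat_spectrum(self):
        spec = flat_spectrum(2.0)
        bsa, snr, summed = quantify(spec, [100, 150])
        assert np.allclose(bsa, 0.0)
        assert np.allclose(snr, 1.0)
        assert np.allclose(summed, 0.0)

    def test_injected_amplitude(self):
        spec = flat_spectrum(0.5)
        spec.amps[:, 100] += 2.0
        bsa, snr, _ = quantify(spec, [100])
        assert np.allclose(bsa[:, 0], 2.0)
        assert np.allclose(snr[:, 0], 2.5 / 0.5)

    def test_summed_additivity(self):
        rng = np.random.default_rng(9)
        spec = AmplitudeSpectrumSet(rng.uniform(0.5, 1.5, (3, 400)),
                                    1 / 52.8, 400 / 52.8)
        b1, _, s1 = quantify(spec, [100])
        b2, _, s2 = quantify(spec, [150])
        _, _, s12 = quantify(spec, [100, 150])
        assert np.allclose(s12, s1 + s2)

    def test_zero_mu_snr_missing(self):
        spec = flat_spectrum(0.0)
        _, snr, _ = quantify(spec, [100])
        assert np.all(np.isnan(snr))


class TestBhFdr:
    def test_degenerate_cases(self):
        assert not bh_fdr(np.ones(10)).any()
        assert bh_fdr(np.zeros(10)).all()

    def test_step_up_by_hand(self):
        p = np.array([0.001, 0.008, 0.039, 0.041])
        assert bh_fdr(p, q=0.05).all()      # p_(4) = 0.041 <= 4*0.05/4

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(3, 60)))
            ours = bh_fdr(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, pvals):
        p = np.array(pvals)
        mask = bh_fdr(p)
        if mask.any():
            assert p[mask].max() <= p[~mask].min() if (~mask).any() else True


class TestContrast:
    def test_identical_spectra_null(self):
        spec = flat_spectrum(1.0, n_ch=8)
        res = contrast_intact_scrambled(spec, flat_spectrum(1.0, n_ch=8),
                                        [100, 150])
        assert np.allclose(res.z, 0.0)
        assert not res.sig_mask.any()

    def test_injected_channels_pass_fdr(self):
        rng = np.random.default_rng(11)
        n_ch, n_bins = 128, 500
        base = rng.uniform(0.5, 0.52, (n_ch, n_bins))
        intact = base.copy()
        bins = [100, 150, 200]
        hot = rng.choice(n_ch, 10, replace=False)
        for b in bins:
            intact[hot, b] += 1.0
        si = AmplitudeSpectrumSet(intact, 1 / 52.8, 10.0)
        ss = AmplitudeSpectrumSet(base, 1 / 52.8, 10.0)
        res = contrast_intact_scrambled(si, ss, bins)
        assert set(np.nonzero(res.sig_mask)[0]) == set(hot)

    def test_chunk_width_guard(self):
        spec = flat_spectrum(1.0)
        with pytest.raises(ValueError, match="overlap"):
            contrast_intact_scrambled(spec, flat_spectrum(1.0), [100, 110])

    def test_chunk_sum_z_uses_25_bins(self):
        # a disturbance 13 bins away from the harmonic does not enter
        amps = np.full((1, 400), 1.0)
        amps[0, 100 + 13] = 99.0
        z_far = chunk_sum_z(amps, [100])
        amps2 = np.full((1, 400), 1.0)
        z_ref = chunk_sum_z(amps2, [100])
        assert z_far == pytest.approx(z_ref)


class TestGroupStats:
    def test_identical_groups(self):
        spec = flat_spectrum(1.0)
        res = per_participant_response([spec] * 4, [spec] * 4, [100], [0, 1])
        assert res["t"] == 0.0 and res["p"] == 0.5

    def test_single_participant_rejected(self):
        spec = flat_spectrum(1.0)
        with pytest.raises(ValueError):
            per_participant_response([spec], [spec], [100], [0])

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(1, 1, 24), rng.normal(0, 1, 24)
        t, p, d = paired_onetailed_t(a, b)
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert d == pytest.approx((a - b).mean() / (a - b).std(ddof=1))
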