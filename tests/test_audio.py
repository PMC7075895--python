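"""Acoustic feature extraction: oracles on constructed signals."""

import numpy as np
import pytest

from speechstate.audio import (AcousticConfig, SegmentationResult,
                               VoicingTrack, aiu_metrics,
                               extract_acoustic_from_signal, jitter_shimmer,
                               load_inventory, mfcc, noise_measures,
                               preprocess, segment_pauses, shoelace_area,
                               spectral_block, summarize, track_voicing)

SR = 16000


def _tone(freq, duration, sr=SR, amp=0.3):
    t = np.arange(int(duration * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


def _track_from(periods_ms, amps=None, r=None):
    periods = np.asarray(periods_ms, float) / 1000.0
    n = len(periods)
    amps = np.ones(n) if amps is None else np.asarray(amps, float)
    rr = np.full(3, 0.9) if r is None else np.asarray(r, float)
    voiced = np.ones(len(rr), bool)
    return VoicingTrack(times=np.arange(len(rr)) * 0.01, f0=100 / np.ones(len(rr)),
                        voiced=voiced, r_at_lag=rr, periods=periods,
                        amplitudes=amps, hop_s=0.01)


class TestPreprocess:
    def test_trims_30s_each_end(self):
        out = preprocess(np.zeros(300 * 1000), 1000)
        assert len(out) == 240 * 1000

    def test_excises_interviewer_interval(self):
        out = preprocess(np.zeros(300 * 1000), 1000, [(100.0, 110.0)])
        assert len(out) == 230 * 1000

    def test_interval_outside_window_ignored(self):
        out = preprocess(np.zeros(300 * 1000), 1000, [(5.0, 10.0)])
        assert len(out) == 240 * 1000

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="60"):
            preprocess(np.zeros(59 * 1000), 1000)


class TestVoicing:
    def test_pure_tone_tracked_at_its_frequency(self):
        track = track_voicing(_tone(100, 2.0), SR)
        assert track.voiced_fraction > 0.95
        assert np.nanmedian(track.f0) == pytest.approx(100, abs=1.0)

    def test_white_noise_is_unvoiced(self):
        rng = np.random.default_rng(0)
        track = track_voicing(rng.standard_normal(2 * SR) * 0.1, SR)
        assert track.voiced_fraction < 0.15

    def test_all_silent_input_gives_empty_track_not_error(self):
        track = track_voicing(np.zeros(SR), SR)
        assert len(track.f0) == 0

    def test_band_validation(self):
        with pytest.raises(ValueError):
            AcousticConfig(f0_band=(20.0, 500.0))


class TestJitterShimmer:
    def test_constant_periods_zero_jitter(self):
        js = jitter_shimmer(_track_from([10, 10, 10]))
        assert js["jitter_local"] == pytest.approx(0.0)

    def test_alternating_periods_hand_value(self):
        # mean |dT| = 2 ms over mean T = 10 ms -> 20%
        js = jitter_shimmer(_track_from([9, 11, 9, 11]))
        assert js["jitter_local"] == pytest.approx(20.0)

    def test_equal_amplitudes_zero_shimmer(self):
        js = jitter_shimmer(_track_from([10, 10, 10], amps=[1, 1, 1]))
        assert js["shimmer_local"] == pytest.approx(0.0)

    def test_too_few_cycles_missing(self):
        js = jitter_shimmer(_track_from([10]))
        assert np.isnan(js["jitter_local"])
        assert np.isnan(js["jitter_ppq5"])


class TestNoiseMeasures:
    def test_half_autocorrelation_closed_form(self):
        nm = noise_measures(_track_from([10, 10], r=[0.5, 0.5, 0.5]))
        assert nm["hnr_db"] == pytest.approx(0.0, abs=1e-9)
        assert nm["nhr"] == pytest.approx(1.0)
        assert nm["mean_autocorr"] == pytest.approx(0.5)

    def test_noiseless_periodic_signal_high_hnr(self):
        track = track_voicing(_tone(100, 2.0), SR)
        nm = noise_measures(track)
        assert nm["hnr_db"] >= 30.0

    def test_equal_power_harmonic_noise_mixture_near_zero_db(self):
        rng = np.random.default_rng(1)
        tone = _tone(100, 3.0, amp=1.0)
        noise = rng.standard_normal(len(tone))
        noise *= np.sqrt(np.mean(tone ** 2) / np.mean(noise ** 2))
        track = track_voicing(tone + noise, SR)
        nm = noise_measures(track)
        assert abs(nm["hnr_db"]) < 2.0


class TestSegmentation:
    def test_single_gap_recovered(self):
        x = np.concatenate([_tone(200, 2.0), np.zeros(SR), _tone(200, 2.0)])
        seg = segment_pauses(x, SR)
        assert len(seg.pauses) == 1
        a, b = seg.pauses[0]
        assert b - a == pytest.approx(1.0, abs=0.05)

    def test_continuous_phonation_no_pauses(self):
        seg = segment_pauses(_tone(200, 3.0), SR)
        assert len(seg.pauses) == 0

    def test_rate_definitions(self):
        seg = SegmentationResult(pauses=[(0.0, 1.0)], utterances=[(1.0, 5.0)],
                                 n_nuclei=10, total_s=5.0)
        assert seg.speech_rate == pytest.approx(2.0)
        assert seg.articulation_rate == pytest.approx(2.5)

    def test_silent_input_one_spanning_pause(self):
        seg = segment_pauses(np.zeros(2 * SR), SR)
        assert seg.n_nuclei == 0
        assert seg.pauses == [(0.0, 2.0)]


class TestSpectral:
    def test_tone_peak_frequency(self):
        spec = spectral_block(_tone(440, 2.0), SR)
        assert spec["freq_at_max"] == pytest.approx(440, abs=5)

    def test_amplitude_doubling_energy_and_db(self):
        x = _tone(440, 2.0)
        s1, s2 = spectral_block(x, SR), spectral_block(2 * x, SR)
        assert s2["energy"] == pytest.approx(4 * s1["energy"])
        assert s2["max_db"] - s1["max_db"] == pytest.approx(6.02, abs=0.1)

    def test_mfcc_frame_count_arithmetic(self):
        # floor((1 s - 25 ms) / 10 ms) + 1 = 98 frames
        m = mfcc(np.zeros(SR), SR)
        assert m.shape == (16, 98)


class TestVowelSpace:
    def test_shoelace_hand_value(self):
        pts = np.array([[800, 1200], [300, 2300], [350, 800]])
        assert shoelace_area(pts) == pytest.approx(347_500.0)

    def test_aiu_metrics_on_exact_corner_points(self):
        pts = np.array([[800, 1200], [300, 2300], [350, 800]])
        m = aiu_metrics(pts)
        assert m["aiu_area"] == pytest.approx(347_500.0, rel=1e-9)

    def test_degenerate_point_cloud_zero_total_area(self):
        from speechstate.audio import ConvexHull, QhullError
        pts = np.tile([[500.0, 1500.0]], (20, 1))
        with pytest.raises(QhullError):
            ConvexHull(pts)  # the extractor maps this to area 0

    def test_planted_vowel_targets_recovered(self, flat_profile):
        from speechstate.synth import ConditionEffects, synth_voice
        from speechstate.audio import formant_block
        wave, _ = synth_voice(flat_profile, ConditionEffects(), 66.0, SR, 21)
        x = preprocess(wave, SR)
        track = track_voicing(x, SR)
        formants, _ = formant_block(x, SR, track)
        valid = formants[~np.isnan(formants).any(axis=1)][:, :2]
        refs = {"a": (800, 1200), "i": (300, 2300), "u": (350, 800)}
        targets = np.array(list(refs.values()))
        nearest = np.linalg.norm(valid[:, None] - targets[None], axis=2).argmin(1)
        for k, (name, tgt) in enumerate(refs.items()):
            centroid = valid[nearest == k].mean(axis=0)
            assert np.all(np.abs(centroid - tgt) <= 75), (name, centroid)


class TestSummarize:
    def test_hand_computed_order_statistics(self):
        s = summarize([100, 110, 120, 130, 140], "abeg")
        assert s["a"] == 120
        assert s["b"] == 20
        assert s["e"] == pytest.approx(102.0)
        assert s["g"] == pytest.approx(138.0)

    def test_constant_series_convention(self):
        s = summarize([5.0] * 10, "bcd")
        assert s["b"] == 0 and s["c"] == 0 and s["d"] == 0

    def test_symmetric_series_zero_skew(self):
        assert summarize([1, 2, 3, 4, 5], "d")["d"] == pytest.approx(0.0)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(101)
        fwd, rev = summarize(x), summarize(x[::-1])
        for d in fwd:
            assert rev[d] == pytest.approx(fwd[d], rel=1e-9, abs=1e-12)

    def test_empty_series_missing(self):
        assert np.isnan(summarize([], "a")["a"])

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0], "z")


class TestFullExtraction:
    def test_inventory_closure(self, small_cohort):
        from speechstate.audio import extract_acoustic
        row = small_cohort.manifest.iloc[0]
        feats = extract_acoustic(row.audio_path)
        assert list(feats) == load_inventory()
        assert len(feats) == 88

    def test_determinism_same_file(self, small_cohort):
        from speechstate.audio import extract_acoustic
        row = small_cohort.manifest.iloc[1]
        f1 = extract_acoustic(row.audio_path)
        f2 = extract_acoustic(row.audio_path)
        assert f1 == f2

    def test_scale_equivariance(self, flat_profile):
        from speechstate.synth import ConditionEffects, synth_voice
        wave, _ = synth_voice(flat_profile, ConditionEffects(), 66.0, SR, 31)
        f1 = extract_acoustic_from_signal(wave, SR)
        f3 = extract_acoustic_from_signal(3.0 * wave, SR)
        for name in ("Pitch_a", "Jitter_h", "Shimmer_h", "F1_a", "F2_a",
                     "HNR", "SpeechRate", "PauseCount", "PhonationRatio"):
            assert f3[name] == pytest.approx(f1[name], rel=1e-6, abs=1e-9), name
        assert f3["Spectral_energy"] == pytest.approx(9 * f1["Spectral_energy"],
                                                      rel=1e-9)
        assert f3["Spectral_maxdB"] - f1["Spectral_maxdB"] == pytest.approx(
            10 * np.log10(9), abs=1e-6)
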