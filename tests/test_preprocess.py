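"""Segmentation, ICA eye-artifact removal, STFT and standardization."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import kandetect as kd
from kandetect.preprocess import (
    CHANNELS_1020,
    clean_recording,
    flatten_features,
    stft_shape,
)
from kandetect.simulate import SimConfig, blink_train, gen_background, inject_blinks


def make_rec(signals, fs=250.0, annotations=()):
    names = CHANNELS_1020[: signals.shape[0]] if signals.shape[0] <= 19 else None
    return kd.EEGRecording(signals, fs, list(CHANNELS_1020[: signals.shape[0]]),
                           list(annotations))


class TestSegmentation:
    def test_400_hours_yield_120000_windows(self):
        n_samples = 400 * 3600 * 250
        assert kd.count_windows(n_samples, fs=250, window_s=12) == 120_000

    def test_single_window_recording(self, rng):
        rec = make_rec(rng.standard_normal((19, 3000)))
        segs = kd.segment_recording(rec)
        assert len(segs) == 1
        assert segs[0][0].shape == (19, 3000)

    def test_hand_enumerated_labels_and_trailing_discard(self, rng):
        """30 s with a seizure at [5, 9] s: two full windows, labels (1, 0)."""
        rec = make_rec(rng.standard_normal((19, 7500)), annotations=[(5.0, 9.0, "seizure")])
        segs = kd.segment_recording(rec)
        assert [lab for _, lab, _ in segs] == [1, 0]

    def test_overlap_fraction_rule(self, rng):
        # seizure covers 2 of 12 s of window 0: any-overlap labels it, a 25% rule does not
        rec = make_rec(rng.standard_normal((19, 6000)), annotations=[(10.0, 12.0, "seizure")])
        assert kd.segment_recording(rec)[0][1] == 1
        assert kd.segment_recording(rec, label_rule=0.25)[0][1] == 0

    def test_segmentation_conserves_samples(self, rng):
        rec = make_rec(rng.standard_normal((19, 10_123)))
        segs = kd.segment_recording(rec)
        wlen = 3000
        assert len(segs) * wlen + rec.n_samples % wlen == rec.n_samples

    def test_zero_length_recording_gives_empty_list(self):
        rec = make_rec(np.zeros((19, 0)))
        assert kd.segment_recording(rec) == []


class TestPearson:
    def test_perfect_linear_dependence(self):
        assert kd.pearson_r([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(200), rng.standard_normal(200)
            assert kd.pearson_r(a, b) == pytest.approx(pearsonr(a, b).statistic, abs=1e-12)

    def test_zero_variance_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert kd.pearson_r(np.ones(10), np.arange(10)) == 0.0


class TestICA:
    def test_nineteen_components(self, blinked_recording):
        _, blinked, _ = blinked_recording
        dec = kd.run_ica(blinked, seed=0)
        assert dec.n_components == 19
        assert dec.mixing_time_courses.shape == (blinked.n_samples, 19)
        assert dec.topographies.shape == (19, 19)

    def test_deterministic_given_seed(self, blinked_recording):
        _, blinked, _ = blinked_recording
        d1 = kd.run_ica(blinked, seed=5)
        d2 = kd.run_ica(blinked, seed=5)
        np.testing.assert_array_equal(d1.mixing_time_courses, d2.mixing_time_courses)
        np.testing.assert_array_equal(d1.topographies, d2.topographies)

    def test_single_broadcast_source_dominates(self, rng):
        # a non-Gaussian source is required for blind separation to be identifiable
        src = rng.laplace(size=3000)
        gains = rng.uniform(0.5, 1.5, 19)
        sig = gains[:, None] * src[None, :] + 1e-3 * rng.standard_normal((19, 3000))
        dec = kd.run_ica(make_rec(sig), seed=0)
        m, a = dec.mixing_time_courses, dec.topographies
        contrib = m.var(axis=0) * np.sum(a**2, axis=1)
        assert contrib[0] / contrib.sum() >= 0.99

    def test_constant_channel_rejected(self, rng):
        sig = rng.standard_normal((19, 3000))
        sig[4] = 1.0
        with pytest.raises(ValueError, match="constant channel"):
            kd.run_ica(make_rec(sig), seed=0)

    def test_reconstruction_residual_small(self, blinked_recording):
        _, blinked, _ = blinked_recording
        dec = kd.run_ica(blinked, seed=0)
        assert dec.residual < 1e-8  # full-rank decomposition reconstructs exactly


class TestEyeScores:
    def test_component_equal_to_fp1_scores_one(self, blinked_recording):
        _, blinked, _ = blinked_recording
        dec = kd.run_ica(blinked, seed=0)
        dec.mixing_time_courses[:, 3] = blinked.channel("FP1")
        scores = kd.score_eye_components(dec, blinked)
        assert scores[3] == pytest.approx(1.0)

    def test_independent_noise_scores_near_zero(self, rng):
        rec = make_rec(rng.standard_normal((19, 3000)))
        dec = kd.run_ica(rec, seed=1)
        dec.mixing_time_courses[:, 0] = np.random.default_rng(999).standard_normal(3000)
        scores = kd.score_eye_components(dec, rec)
        assert scores[0] < 0.05


class TestRemoveComponents:
    def test_nothing_removed_reproduces_round_trip(self, blinked_recording):
        clean, _, _ = blinked_recording
        dec = kd.run_ica(clean, seed=0)
        kd.score_eye_components(dec, clean)
        out = kd.remove_components(dec, clean, threshold=1.0)
        rel = np.linalg.norm(out.signals - clean.signals) / np.linalg.norm(clean.signals)
        assert rel < 1e-8
        assert dec.rejected == set()

    def test_planted_blink_removed_posterior_preserved(self):
        """Frontal blink correlation drops below 0.1; posterior keeps >= 90% variance."""
        passed = 0
        for seed in range(5):
            cfg = SimConfig(duration_s=60.0)
            bg = gen_background(cfg, seed=100 + seed)
            blinked = inject_blinks(bg, cfg, seed=200 + seed)
            train = blink_train(bg, cfg, seed=200 + seed)
            dec = kd.run_ica(blinked, seed=seed)
            kd.score_eye_components(dec, blinked)
            cleaned = kd.remove_components(dec, blinked)
            r_before = abs(kd.pearson_r(blinked.channel("FP1"), train))
            r_after = abs(kd.pearson_r(cleaned.channel("FP1"), train))
            posterior = min(
                cleaned.channel(ch).var() / blinked.channel(ch).var()
                for ch in ("O1", "O2", "P3", "P4", "T5", "T6")
            )
            passed += (r_before >= 0.3) and (r_after < 0.1) and (posterior >= 0.9)
        assert passed >= 4

    def test_refuses_to_remove_everything(self, blinked_recording):
        _, blinked, _ = blinked_recording
        dec = kd.run_ica(blinked, seed=0)
        dec.eye_scores = np.ones(19)
        with pytest.raises(ValueError, match="every component"):
            kd.remove_components(dec, blinked, threshold=0.5)

    def test_top_k_mode_removes_exactly_k(self, blinked_recording):
        _, blinked, _ = blinked_recording
        dec = kd.run_ica(blinked, seed=0)
        kd.score_eye_components(dec, blinked)
        kd.remove_components(dec, blinked, top_k=2)
        assert len(dec.rejected) == 2

    def test_annotations_and_rate_preserved(self, rng):
        rec = make_rec(rng.standard_normal((19, 3000)), annotations=[(1.0, 2.0, "seizure")])
        out = clean_recording(rec, seed=0)
        assert out.annotations == rec.annotations
        assert out.fs == rec.fs
        assert out.signals.shape == rec.signals.shape


class TestSTFT:
    def test_default_shape_contract(self, rng):
        seg = rng.standard_normal((19, 3000))
        feats = kd.stft_features(seg)
        assert feats.shape == (19, 23, 125)

    def test_frame_count_formula(self):
        assert stft_shape(3000) == (23, 125)
        assert stft_shape(1000) == (7, 125)

    def test_zero_segment_gives_zero_features(self):
        for mode in ("magnitude", "log_magnitude", "power"):
            cfg = kd.STFTConfig(magnitude_mode=mode)
            assert np.all(kd.stft_features(np.zeros((19, 3000)), cfg) == 0.0)

    def test_window_longer_than_segment_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            kd.stft_features(np.zeros((19, 100)))

    def test_keep_dc_adds_one_bin(self, rng):
        cfg = kd.STFTConfig(drop_dc=False)
        assert kd.stft_features(rng.standard_normal((19, 3000)), cfg).shape == (19, 23, 126)

    def test_pure_tone_peaks_at_its_frequency_bin(self):
        t = np.arange(3000) / 250.0
        seg = np.sin(2 * np.pi * 10.0 * t)[None, :]
        feats = kd.stft_features(seg)  # bin i is (i + 1) Hz with DC dropped
        assert np.argmax(feats.mean(axis=1)) == 9


class TestStandardize:
    def test_training_split_is_zero_mean_unit_variance(self, rng):
        x = rng.normal(3.0, 2.0, (50, 2, 3, 4))
        out, stats = kd.standardize_features(x)
        flat = flatten_features(out)
        assert np.abs(flat.mean(axis=0)).max() < 1e-6
        assert np.abs(flat.var(axis=0) - 1).max() < 1e-6

    def test_constant_feature_maps_to_zero(self, rng):
        x = rng.normal(size=(30, 1, 1, 3))
        x[:, 0, 0, 1] = 7.0
        out, _ = kd.standardize_features(x)
        assert np.all(out[:, 0, 0, 1] == 0.0)

    def test_not_idempotent_with_saved_stats(self, rng):
        x = rng.normal(5.0, 3.0, (40, 1, 1, 2))
        once, stats = kd.standardize_features(x)
        twice, _ = kd.standardize_features(once, stats)
        assert not np.allclose(once, twice)

    def test_saved_stats_apply_identically_at_inference(self, rng):
        x = rng.normal(size=(40, 1, 1, 2))
        _, stats = kd.standardize_features(x)
        y = rng.normal(size=(10, 1, 1, 2))
        out, _ = kd.standardize_features(y, stats)
        expected = ((flatten_features(y) - stats[0]) / stats[1]).reshape(y.shape)
        np.testing.assert_allclose(out, expected, atol=1e-12)
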