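"""Detector chain: spectrogram analytics, noise profile, masks, tracks."""

import numpy as np
import pytest

from conftest import FIXTURE_DETECTOR, SAMPLE_RATE, overlap_s, snr_to_noise_sd
from whalecues.detection import (
    DetectorConfig,
    binarize,
    compute_spectrogram,
    detect_calls,
    estimate_noise_profile,
    extract_tracks,
)
from whalecues.synth.audio import CallSpec, generate_audio


def _tone(freq: float, dur: float, rate: float = SAMPLE_RATE) -> np.ndarray:
    t = np.arange(int(dur * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestComputeSpectrogram:
    def test_pure_tone_argmax_bin(self):
        spec = compute_spectrogram(_tone(1000.0, 3.0), SAMPLE_RATE, FIXTURE_DETECTOR)
        peak_bins = np.argmax(spec.magnitude, axis=0)
        assert np.all(np.abs(spec.freqs[peak_bins] - 1000.0) < SAMPLE_RATE / 1024)

    def test_silence_gives_zero_magnitudes(self):
        spec = compute_spectrogram(np.zeros(16000), SAMPLE_RATE, FIXTURE_DETECTOR)
        assert np.all(spec.magnitude == 0.0)

    def test_matches_definitional_stft_oracle(self):
        """Frame-by-frame Hann-window rfft recomputation agrees to 1e-10."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=8192)
        cfg = DetectorConfig(window=512, hop=128)
        spec = compute_spectrogram(x, SAMPLE_RATE, cfg)
        win = np.hanning(512 + 1)[:-1]  # periodic Hann, as used by the STFT
        scale = 1.0 / np.sqrt(SAMPLE_RATE * np.sum(win**2))  # density scaling
        for j in [0, 5, spec.n_frames - 1]:
            start = j * 128
            frame = x[start : start + 512]
            ref = np.abs(np.fft.rfft(frame * win)) * scale
            np.testing.assert_allclose(spec.magnitude[:, j], ref, atol=1e-10)

    def test_truncates_to_first_ten_minutes(self):
        x = np.zeros(int(SAMPLE_RATE * 11 * 60))
        spec = compute_spectrogram(x, SAMPLE_RATE, FIXTURE_DETECTOR)
        assert spec.times[-1] <= 600.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_spectrogram(np.array([]), SAMPLE_RATE, FIXTURE_DETECTOR)
        with pytest.raises(ValueError, match="window"):
            compute_spectrogram(np.zeros(100), SAMPLE_RATE, FIXTURE_DETECTOR)
        cfg = DetectorConfig(expected_sample_rate=96_000.0)
        with pytest.raises(ValueError, match="sample rate"):
            compute_spectrogram(np.zeros(96_000), 48_000.0, cfg)


class TestNoiseProfile:
    def test_white_noise_profile_is_flat(self):
        rng = np.random.default_rng(0)
        spec = compute_spectrogram(rng.normal(size=int(10 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        thr = estimate_noise_profile(spec)
        assert np.std(thr) / np.mean(thr) < 0.2

    def test_all_zero_spectrogram_gives_zero_thresholds(self):
        spec = compute_spectrogram(np.zeros(int(2 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        assert np.all(estimate_noise_profile(spec) == 0.0)

    def test_sparse_loud_call_barely_moves_thresholds(self):
        """Median/MAD robustness: a sparse loud call shifts thresholds <5%."""
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.1, int(30 * SAMPLE_RATE))
        with_call = noise.copy()
        tone = 5.0 * _tone(2000.0, 0.8)  # ~3% of frames, +34 dB over noise
        with_call[: tone.size] += tone
        t_noise = estimate_noise_profile(
            compute_spectrogram(noise, SAMPLE_RATE, FIXTURE_DETECTOR))
        t_call = estimate_noise_profile(
            compute_spectrogram(with_call, SAMPLE_RATE, FIXTURE_DETECTOR))
        assert np.max(np.abs(t_call - t_noise) / np.maximum(t_noise, 1e-12)) < 0.05

    def test_too_few_frames_rejected(self):
        spec = compute_spectrogram(np.zeros(2048), SAMPLE_RATE,
                                   DetectorConfig(window=1024, hop=256))
        with pytest.raises(ValueError, match="frames"):
            estimate_noise_profile(spec)


class TestBinarize:
    def test_below_threshold_mask_is_false(self):
        spec = compute_spectrogram(np.zeros(int(2 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        mask = binarize(spec, np.ones(spec.n_bins))
        assert not mask.any()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        spec = compute_spectrogram(rng.normal(size=int(3 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        thr = estimate_noise_profile(spec)
        m1 = binarize(spec, thr)
        spec.magnitude = spec.magnitude * 7.3
        m2 = binarize(spec, thr * 7.3)
        np.testing.assert_array_equal(m1, m2)

    def test_shape_mismatch_rejected(self):
        spec = compute_spectrogram(np.zeros(int(2 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        with pytest.raises(ValueError, match="thresholds"):
            binarize(spec, np.ones(spec.n_bins + 1))

    def test_chirp_ridge_mostly_above_noise_at_15db(self):
        call = CallSpec(1.0, 1.0, (1000.0, 500.0, 0.0))
        wave, _ = generate_audio([call], snr_to_noise_sd(15.0), SAMPLE_RATE, 3.0, seed=0)
        spec = compute_spectrogram(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        mask = binarize(spec, estimate_noise_profile(spec))
        inside = (spec.times > call.onset_s + 0.05) & (spec.times < call.offset_s - 0.05)
        hits = 0
        frames = np.nonzero(inside)[0]
        for j in frames:
            f_true = call.freq_at(spec.times[j] - call.onset_s)
            b = int(np.argmin(np.abs(spec.freqs - f_true)))
            hits += bool(mask[max(b - 1, 0) : b + 2, j].any())
        assert hits / frames.size >= 0.9


class TestExtractTracks:
    def test_single_chirp_yields_one_track_spanning_the_call(self):
        call = CallSpec(1.0, 1.0, (1000.0, 500.0, 0.0))
        wave, _ = generate_audio([call], snr_to_noise_sd(15.0), SAMPLE_RATE, 3.0, seed=0)
        spec = compute_spectrogram(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        mask = binarize(spec, estimate_noise_profile(spec, k=FIXTURE_DETECTOR.k_mad))
        tracks = extract_tracks(spec, mask, min_track_pixels=10)
        assert len(tracks) == 1
        assert overlap_s(tracks[0].onset_s, tracks[0].offset_s,
                         call.onset_s, call.offset_s) >= 0.8 * call.duration_s

    def test_two_separated_tones_yield_two_tracks(self):
        specs = [CallSpec(0.5, 0.5, (1000.0, 0.0, 0.0)),
                 CallSpec(2.0, 0.5, (1000.0, 0.0, 0.0))]
        wave, _ = generate_audio(specs, snr_to_noise_sd(15.0), SAMPLE_RATE, 3.5, seed=0)
        spec = compute_spectrogram(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        mask = binarize(spec, estimate_noise_profile(spec, k=FIXTURE_DETECTOR.k_mad))
        assert len(extract_tracks(spec, mask, min_track_pixels=10)) == 2

    def test_isolated_speckle_is_filtered_out(self):
        spec = compute_spectrogram(np.zeros(int(3 * SAMPLE_RATE)) + 1e-9,
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        mask = np.zeros_like(spec.magnitude, dtype=bool)
        mask[50, 10] = mask[120, 80] = True  # single pixels, sub-minimum duration
        assert extract_tracks(spec, mask, min_duration_s=0.1) == []

    def test_empty_mask_gives_empty_list(self):
        spec = compute_spectrogram(np.zeros(int(2 * SAMPLE_RATE)),
                                   SAMPLE_RATE, FIXTURE_DETECTOR)
        assert extract_tracks(spec, np.zeros_like(spec.magnitude, bool)) == []


class TestDetectCalls:
    def test_deterministic_for_fixed_input(self, call_fixture):
        wave, _ = call_fixture
        a = detect_calls(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        b = detect_calls(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        assert [t.onset_s for t in a] == [t.onset_s for t in b]
        assert all(x.duration_s >= FIXTURE_DETECTOR.min_duration_s for x in a)

    def test_raising_threshold_never_adds_tracks(self, call_fixture):
        wave, _ = call_fixture
        counts = [
            len(detect_calls(wave, SAMPLE_RATE,
                             DetectorConfig(window=1024, hop=256, k_mad=k)))
            for k in (3.0, 4.0, 6.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_call_after_minute_ten_not_detected(self):
        call = CallSpec(11 * 60.0, 1.0, (1000.0, 0.0, 0.0))
        wave, _ = generate_audio([call], snr_to_noise_sd(15.0), SAMPLE_RATE,
                                 12 * 60.0, seed=0)
        assert detect_calls(wave, SAMPLE_RATE, FIXTURE_DETECTOR) == []

    def test_calls_sorted_by_onset(self, call_fixture):
        wave, _ = call_fixture
        segs = detect_calls(wave, SAMPLE_RATE, FIXTURE_DETECTOR)
        onsets = [s.onset_s for s in segs]
        assert onsets == sorted(onsets)
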