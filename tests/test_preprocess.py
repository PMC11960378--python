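"""Filtering, STFT, combined features, normalization and framing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import sosfreqz

from swdnet.eeg_io import CANONICAL_CHANNELS, Event, EventList, Recording
from swdnet.preprocess import (
    FeatureExample, FilterSpec, StftSpec, bandpass_filter, combined_features,
    make_examples, normalize, stft_frames,
)


def dft_oracle(signal, spec):
    """Brute-force direct-sum windowed DFT, independent of np.fft.

    F[t, f] = sum_j x[t*hop + j] * h[j] * exp(-i 2 pi f j / N), computed
    through an explicit DFT matrix product.
    """
    n = spec.window_len
    h = spec.taper()
    j = np.arange(n)
    f = np.arange(n)
    dft_matrix = np.exp(-2j * np.pi * np.outer(f, j) / n)
    n_frames = (len(signal) - n) // spec.hop + 1
    out = np.empty((n_frames, n), dtype=complex)
    for t in range(n_frames):
        seg = signal[t * spec.hop : t * spec.hop + n] * h
        out[t] = dft_matrix @ seg
    return out


def _sine_rec(freq, fs, dur_s=10.0, n_ch=19):
    t = np.arange(int(dur_s * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data, fs, list(CANONICAL_CHANNELS[:n_ch]))


class TestBandpassFilter:
    def test_dc_removed(self):
        rec = Recording(np.full((19, 2000), 50.0), 100.0, list(CANONICAL_CHANNELS))
        out = bandpass_filter(rec)
        # after the low-cut transient the DC level is essentially gone
        assert np.abs(out.data[:, 500:1500]).max() < 50 * 1e-3 * 50

    def test_3hz_passband_gain_near_unity(self):
        rec = _sine_rec(3.0, 100.0, dur_s=60.0)
        out = bandpass_filter(rec)
        n = out.n_samples
        core = out.data[0, n // 3 : 2 * n // 3]  # steady state, no edge transient
        assert 0.95 <= np.abs(core).max() <= 1.0 + 1e-3

    def test_50hz_interference_suppressed(self):
        rec = _sine_rec(50.0, 500.0, dur_s=60.0)
        out = bandpass_filter(rec)
        n = out.n_samples
        assert np.abs(out.data[0, n // 3 : 2 * n // 3]).max() < 0.05

    def test_forward_mode_differs_from_zero_phase(self):
        rec = _sine_rec(3.0, 100.0)
        fwd = bandpass_filter(rec, FilterSpec(application_mode="forward"))
        zp = bandpass_filter(rec, FilterSpec())
        assert not np.allclose(fwd.data, zp.data)

    def test_fs_too_low_rejected(self):
        rec = _sine_rec(3.0, 60.0)  # Nyquist 30 < high cut 35
        with pytest.raises(ValueError):
            bandpass_filter(rec)

    def test_designed_sections_are_stable(self):
        sos = FilterSpec().design_sos(500.0)
        for section in sos:
            assert np.all(np.abs(np.roots(section[3:])) < 1.0)

    def test_half_power_at_printed_cutoffs(self):
        spec = FilterSpec()
        sos = spec.design_sos(500.0)
        w, h = sosfreqz(sos, worN=[spec.low_cut_hz, spec.high_cut_hz], fs=500.0)
        np.testing.assert_allclose(np.abs(h), 1 / np.sqrt(2), atol=1e-6)

    def test_filter_downsample_commute_for_inband_sine(self):
        from swdnet.eeg_io import resample
        rec = _sine_rec(3.0, 500.0, dur_s=30.0)
        a = resample(bandpass_filter(rec), 100.0)
        b = bandpass_filter(resample(rec, 100.0))
        core = slice(500, -500)
        amp_a = np.abs(a.data[0, core]).max()
        amp_b = np.abs(b.data[0, core]).max()
        assert abs(amp_a - amp_b) / amp_b < 0.02


class TestStft:
    def test_zero_signal_gives_zero_frames(self):
        spec = StftSpec(window_len=64, hop=32)
        out = stft_frames(np.zeros(256), spec, 100.0)
        assert out.shape == ((256 - 64) // 32 + 1, 64)
        assert np.all(out == 0)

    def test_bin_aligned_sinusoid_confined_to_its_bin(self):
        n = 64
        spec = StftSpec(window_len=n, hop=n, window_fn="rect")
        k = 5
        x = np.sin(2 * np.pi * k * np.arange(4 * n) / n)
        out = stft_frames(x, spec, 100.0)
        mag = np.abs(out[0])
        others = np.delete(mag, [k, n - k])
        assert np.all(others < 1e-9 * mag[k])

    def test_frame_count_arithmetic(self):
        spec = StftSpec(window_len=256, hop=128)
        out = stft_frames(np.zeros(6000), spec, 100.0)
        assert out.shape[0] == (6000 - 256) // 128 + 1 == 45

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            stft_frames(np.zeros(100), StftSpec(window_len=256), 100.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = StftSpec(window_len=64, hop=32)
        x = rng.standard_normal(rng.integers(64, 513))
        got = stft_frames(x, spec, 100.0)
        want = dft_oracle(x, spec)
        scale = np.abs(want).max()
        assert np.abs(got - want).max() / scale < 1e-9


class TestCombinedFeatures:
    def test_zero_signal_gives_zero_features(self):
        rec = Recording(np.zeros((19, 1000)), 100.0, list(CANONICAL_CHANNELS))
        feats, times = combined_features(rec)
        assert feats.shape == ((1000 - 256) // 128 + 1, 256, 19)
        assert np.all(feats == 0)

    def test_3hz_energy_peaks_near_bin_8(self):
        rec = _sine_rec(3.0, 100.0, dur_s=30.0)
        feats, _ = combined_features(rec)
        spec_half = feats[feats.shape[0] // 2, :128, 0]
        assert abs(int(np.argmax(spec_half)) - round(3 * 256 / 100)) <= 1

    def test_raw_half_is_decimated_window(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((19, 1000))
        rec = Recording(data, 100.0, list(CANONICAL_CHANNELS))
        feats, _ = combined_features(rec)
        np.testing.assert_allclose(feats[2, 128:, 4],
                                   data[4, 2 * 128 : 2 * 128 + 256 : 2],
                                   rtol=1e-6)

    def test_frame_times_tile_with_constant_hop(self):
        rec = _sine_rec(3.0, 100.0, dur_s=30.0)
        _, times = combined_features(rec)
        strides = np.diff(times[:, 0])
        np.testing.assert_allclose(strides, 128 / 100.0)
        np.testing.assert_allclose(times[:, 1] - times[:, 0], 2.56)

    def test_wrong_n_features_rejected(self):
        rec = _sine_rec(3.0, 100.0)
        with pytest.raises(ValueError):
            combined_features(rec, StftSpec(n_features=512))


def _example_from(tensor, labels=None, mask=None, rid="r0"):
    nf = tensor.shape[0]
    times = np.stack([np.arange(nf) * 1.28, np.arange(nf) * 1.28 + 2.56], axis=1)
    if labels is None:
        labels = np.zeros(nf, dtype=np.int8)
    if mask is None:
        mask = np.ones(nf, dtype=bool)
    return FeatureExample(tensor, times, labels, mask, rid)


class TestNormalize:
    def test_raw_half_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        ex = _example_from(rng.standard_normal((64, 256, 19)).astype(np.float32) * 40)
        (out,) = normalize([ex])
        raw = out.tensor[:, 128:, :]
        np.testing.assert_allclose(raw.mean(axis=(0, 1)), 0, atol=1e-5)
        np.testing.assert_allclose(raw.std(axis=(0, 1)), 1, atol=1e-4)

    def test_scale_invariance_under_device_gain(self):
        # recording amplified 10x (a different device gain) should produce
        # the same normalized features: exactly for the z-scored raw half,
        # and to log1p~log accuracy for the spectrogram half
        rng = np.random.default_rng(2)
        data = rng.standard_normal((19, 3000)) * 40
        rec_a = Recording(data, 100.0, list(CANONICAL_CHANNELS), record_id="a")
        rec_b = Recording(data * 10, 100.0, list(CANONICAL_CHANNELS), record_id="b")
        a = make_examples(rec_a)[0].tensor
        b = make_examples(rec_b)[0].tensor
        np.testing.assert_allclose(a[:, 128:, :], b[:, 128:, :], atol=1e-5)
        # log(1+|X|) is only asymptotically gain-invariant: bins with |X|
        # near zero shift nonlinearly, so assert typical-bin invariance
        assert np.median(np.abs(a[:, :128, :] - b[:, :128, :])) < 0.05

    def test_constant_channel_maps_to_zeros(self):
        t = np.zeros((64, 256, 19), dtype=np.float32)
        t[:, 128:, 3] = 7.5  # constant raw half on one channel
        (out,) = normalize([_example_from(t)])
        assert np.all(out.tensor[:, 128:, 3] == 0)


class TestMakeExamples:
    def _rec(self, dur_s=60.0, events=(), fs=100.0):
        rng = np.random.default_rng(3)
        n = int(dur_s * fs)
        data = rng.standard_normal((19, n)) * 20
        return Recording(data, fs, list(CANONICAL_CHANNELS), EventList(events), "mk0")

    def test_60s_record_framing_arithmetic(self):
        exs = make_examples(self._rec(60.0))
        assert len(exs) == 1
        assert exs[0].tensor.shape == (64, 256, 19)
        assert int(exs[0].frame_mask.sum()) == 45
        assert np.all(exs[0].tensor[45:] == 0)

    def test_event_covering_block_labels_all_ones(self):
        exs = make_examples(self._rec(100.0, events=[Event(0.0, 100.0)]))
        assert np.all(exs[0].frame_labels[exs[0].frame_mask] == 1)

    def test_small_overlap_leaves_frame_unlabeled(self):
        # event covers ~10% of frame 0's 2.56 s window
        exs = make_examples(self._rec(60.0, events=[Event(0.0, 0.25)]))
        assert exs[0].frame_labels[0] == 0

    def test_half_overlap_labels_frame(self):
        exs = make_examples(self._rec(60.0, events=[Event(0.0, 1.30)]))
        assert exs[0].frame_labels[0] == 1

    def test_too_short_record_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert make_examples(self._rec(2.0)) == []

    def test_frame_times_strictly_increasing_constant_stride(self):
        exs = make_examples(self._rec(120.0))
        for ex in exs:
            np.testing.assert_allclose(np.diff(ex.frame_times[:, 0]), 1.28)

    def test_pipeline_deterministic(self):
        a = make_examples(self._rec(60.0))
        b = make_examples(self._rec(60.0))
        np.testing.assert_array_equal(a[0].tensor, b[0].tensor)
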