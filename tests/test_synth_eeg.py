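"""Statistical structure of the synthetic EEG generator."""

import numpy as np
import pytest
from scipy.signal import welch

from swdnet.eeg_io import CANONICAL_CHANNELS
from swdnet.synth_eeg import (
    ConfigurationError, SynthConfig, generate_background, generate_swd_burst,
    inject_artifacts, simulate_recording,
)

IDX = {c: i for i, c in enumerate(CANONICAL_CHANNELS)}


def band_power(x, fs, lo, hi):
    f, pxx = welch(x, fs=fs, nperseg=min(len(x), 2048))
    sel = (f >= lo) & (f < hi)
    return pxx[sel].mean()


class TestBackground:
    def test_zero_mean_and_realistic_amplitude(self):
        cfg = SynthConfig(duration_s=60, seed=3)
        bg = generate_background(cfg, int(60 * cfg.fs))
        assert np.all(np.abs(bg.mean(axis=1)) < 2.0)
        sd = bg.std(axis=1)
        assert np.all(sd > 5) and np.all(sd < 60)

    def test_psd_band_averages_decrease_1_to_40hz(self):
        cfg = SynthConfig(duration_s=60, seed=4)
        bg = generate_background(cfg, int(60 * cfg.fs))
        # alpha-free frontal channel: strict 1/f trend
        x = bg[IDX["fp1"]]
        bands = [(1, 4), (4, 10), (10, 20), (20, 40)]
        powers = [band_power(x, cfg.fs, lo, hi) for lo, hi in bands]
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_alpha_is_posterior_dominant(self):
        cfg = SynthConfig(duration_s=60, seed=5)
        bg = generate_background(cfg, int(60 * cfg.fs))
        p_o1 = band_power(bg[IDX["o1"]], cfg.fs, 8, 10)
        p_fp1 = band_power(bg[IDX["fp1"]], cfg.fs, 8, 10)
        assert p_o1 > 2 * p_fp1

    def test_same_seed_identical(self):
        cfg = SynthConfig(seed=6)
        a = generate_background(cfg, 5000)
        b = generate_background(cfg, 5000)
        np.testing.assert_array_equal(a, b)


class TestSwdBurst:
    def test_dominant_peak_near_3hz_on_every_channel(self):
        cfg = SynthConfig(seed=7)
        burst = generate_swd_burst(cfg, 10.0)
        freqs = np.fft.rfftfreq(burst.shape[1], 1 / cfg.fs)
        for ch in range(19):
            mag = np.abs(np.fft.rfft(burst[ch]))
            mag[freqs < 0.5] = 0  # ignore any residual DC/drift
            peak = freqs[int(np.argmax(mag))]
            assert 2.5 <= peak <= 3.5

    def test_frontal_amplitude_exceeds_occipital(self):
        cfg = SynthConfig(seed=8, frontal_gain=1.5)
        burst = generate_swd_burst(cfg, 8.0)
        assert np.abs(burst[IDX["fz"]]).mean() > np.abs(burst[IDX["o1"]]).mean()

    def test_complex_count_matches_repetition_rate(self):
        cfg = SynthConfig(seed=9)
        burst = generate_swd_burst(cfg, 10.0)
        x = burst[IDX["cz"]]
        # spikes are the dominant sharp positive peaks, one per complex
        thresh = 0.5 * x.max()
        above = x > thresh
        n_peaks = int(np.sum(above[1:] & ~above[:-1]))
        assert 27 <= n_peaks <= 33  # ~3 Hz x 10 s, ends tapered

    def test_peak_amplitude_exceeds_3x_background_scale(self):
        cfg = SynthConfig(seed=10)
        burst = generate_swd_burst(cfg, 6.0)
        assert np.abs(burst).max() >= 3 * cfg.noise_scale

    def test_duration_outside_range_rejected(self):
        with pytest.raises(ValueError):
            generate_swd_burst(SynthConfig(), 100.0)


class TestArtifacts:
    def test_zero_rates_is_identity(self):
        cfg = SynthConfig(seed=11,
                          artifact_rates={"blink": 0.0, "emg": 0.0, "ecg": 0.0})
        bg = generate_background(cfg, 10000)
        out, log = inject_artifacts(bg, cfg)
        np.testing.assert_array_equal(out, bg)
        assert log == []

    def test_blink_energy_frontal_dominant(self):
        cfg = SynthConfig(seed=12, artifact_rates={"blink": 10.0, "emg": 0, "ecg": 0})
        bg = np.zeros((19, int(60 * cfg.fs)))
        out, log = inject_artifacts(bg, cfg)
        blinks = [iv for iv in log if iv.kind == "blink" and iv.channel == "fp1"]
        assert blinks
        iv = blinks[0]
        i0, i1 = int(iv.start_s * cfg.fs), int(iv.end_s * cfg.fs)
        assert np.sum(out[IDX["fp1"], i0:i1] ** 2) > np.sum(out[IDX["o2"], i0:i1] ** 2)

    def test_emg_boosts_high_band_power(self):
        cfg = SynthConfig(seed=13, artifact_rates={"blink": 0, "emg": 8.0, "ecg": 0})
        bg = generate_background(cfg, int(60 * cfg.fs))
        out, log = inject_artifacts(bg, cfg)
        emg = [iv for iv in log if iv.kind == "emg"]
        assert emg
        iv = emg[0]
        i0, i1 = int(iv.start_s * cfg.fs), int(iv.end_s * cfg.fs)
        ch = IDX[iv.channel]
        before = band_power(bg[ch, i0:i1], cfg.fs, 25, 45)
        after = band_power(out[ch, i0:i1], cfg.fs, 25, 45)
        assert after > 5 * before


class TestSimulateRecording:
    def test_hour_record_hits_imbalance_target(self):
        cfg = SynthConfig(duration_s=3600, seizure_fraction=0.0108, seed=14)
        rec, events = simulate_recording(cfg)
        total = events.total_duration_s
        assert 31.0 <= total <= 47.0  # 38.9 s +/- 20%
        assert len(events) >= 1

    def test_zero_fraction_gives_pure_background(self):
        cfg = SynthConfig(duration_s=120, seizure_fraction=0.0, seed=15)
        rec, events = simulate_recording(cfg)
        assert len(events) == 0

    def test_same_seed_identical_recording_and_events(self):
        cfg = SynthConfig(duration_s=60, seizure_fraction=0.1, seed=16)
        r1, e1 = simulate_recording(cfg)
        r2, e2 = simulate_recording(cfg)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert e1 == e2

    def test_events_separated_and_within_record(self, balanced_recording):
        rec, events = balanced_recording
        for a, b in zip(events, events[1:]):
            assert b.start_s - a.end_s >= 5.0
        assert events[-1].end_s <= rec.duration_s

    def test_planted_events_have_3hz_peak_6db_over_background(self,
                                                              balanced_recording):
        rec, events = balanced_recording
        ch = IDX["fz"]
        for ev in events:
            i0, i1 = int(ev.start_s * rec.fs), int(ev.end_s * rec.fs)
            seiz = band_power(rec.data[ch, i0:i1], rec.fs, 2.5, 3.5)
            # compare against the background right before the event
            j0 = max(0, i0 - (i1 - i0))
            bg = band_power(rec.data[ch, j0:i0], rec.fs, 2.5, 3.5)
            assert 10 * np.log10(seiz / bg) >= 6.0

    def test_infeasible_fraction_raises_configuration_error(self):
        # 45% seizure load in 4 s events needs ~45 events whose mandatory
        # 5 s separations alone exceed the record length
        cfg = SynthConfig(duration_s=400, seizure_fraction=0.45,
                          event_dur_range_s=(4.0, 4.0), seed=17)
        with pytest.raises(ConfigurationError):
            simulate_recording(cfg)
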