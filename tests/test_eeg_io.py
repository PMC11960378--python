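"""Recording I/O, montage normalization and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swdnet.eeg_io import (
    CANONICAL_CHANNELS, AmbiguousChannelError, Event, EventList,
    MissingChannelError, Recording, canonicalize_label, read_recording,
    resample, select_channels, write_recording,
)


@pytest.mark.parametrize("raw,expected", [
    ("EEG Fp1-Ref", "fp1"),
    ("EEG FP2-REF", "fp2"),
    ("T7", "t3"),          # modern name -> legacy montage name
    ("T8", "t4"),
    ("P7", "t5"),
    ("P8", "t6"),
    ("Cz", "cz"),
    ("EEG Pz-LE", "pz"),
    ("ECG", None),
    ("A1", None),
    ("EMG chin", None),
])
def test_canonicalize_label(raw, expected):
    assert canonicalize_label(raw) == expected


def _make_recording(labels, fs=100.0, dur_s=5.0, events=()):
    n = int(dur_s * fs)
    rng = np.random.default_rng(0)
    data = rng.standard_normal((len(labels), n)) * 10
    return Recording(data, fs, list(labels), EventList(events), "rec0")


class TestSelectChannels:
    def test_reduces_21_channels_to_canonical_19(self):
        labels = [f"EEG {c.upper()}-Ref" for c in CANONICAL_CHANNELS] + ["ECG", "A1"]
        rec = _make_recording(labels)
        out = select_channels(rec)
        assert out.n_channels == 19
        assert out.channel_labels == list(CANONICAL_CHANNELS)
        # rows follow the canonical order, not the input order
        np.testing.assert_array_equal(out.data, rec.data[:19])

    def test_idempotent_on_canonical_input(self):
        rec = _make_recording(CANONICAL_CHANNELS)
        once = select_channels(rec)
        twice = select_channels(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert once.channel_labels == twice.channel_labels

    def test_reorders_scrambled_channels(self):
        scrambled = list(CANONICAL_CHANNELS[::-1])
        rec = _make_recording(scrambled)
        out = select_channels(rec)
        np.testing.assert_array_equal(out.data[0], rec.data[scrambled.index("fp1")])

    def test_missing_channel_named_in_error(self):
        labels = [c for c in CANONICAL_CHANNELS if c != "pz"]
        with pytest.raises(MissingChannelError, match="pz"):
            select_channels(_make_recording(labels))

    def test_duplicate_resolution_is_an_error(self):
        labels = list(CANONICAL_CHANNELS) + ["T7"]  # T7 -> t3, already present
        with pytest.raises(AmbiguousChannelError):
            select_channels(_make_recording(labels))


class TestResample:
    def test_length_arithmetic_500_to_100(self):
        rec = _make_recording(CANONICAL_CHANNELS, fs=500.0, dur_s=10.0)
        out = resample(rec, 100.0)
        assert out.n_samples == 1000
        assert out.fs == 100.0

    def test_identity_resample(self):
        rec = _make_recording(CANONICAL_CHANNELS, fs=100.0)
        out = resample(rec, 100.0)
        np.testing.assert_allclose(out.data, rec.data)

    def test_annotations_pass_through_in_seconds(self):
        rec = _make_recording(CANONICAL_CHANNELS, fs=500.0, dur_s=10.0,
                              events=[Event(1.0, 3.0)])
        out = resample(rec, 100.0)
        assert out.annotations == rec.annotations

    @pytest.mark.parametrize("freq", [3.0, 10.0, 30.0])
    def test_inband_sinusoid_amplitude_preserved(self, freq):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        sig = np.sin(2 * np.pi * freq * t)
        rec = Recording(np.tile(sig, (19, 1)), fs, list(CANONICAL_CHANNELS))
        out = resample(rec, 100.0)
        t2 = np.arange(out.n_samples) / 100.0
        expected = np.sin(2 * np.pi * freq * t2)
        core = slice(200, -200)  # ignore filter edge transients
        ratio = (np.abs(out.data[0, core]).max() / np.abs(expected[core]).max())
        assert abs(ratio - 1) < 0.01
        # in-band energy preserved within 1%
        e_ratio = (np.mean(out.data[0, core] ** 2) / np.mean(expected[core] ** 2))
        assert abs(e_ratio - 1) < 0.01


class TestEventList:
    def test_merges_overlapping_and_touching_same_label(self):
        el = EventList([(0.0, 2.0, "seizure"), (2.0, 3.0, "seizure"),
                        (2.5, 4.0, "seizure"), (10.0, 12.0, "seizure")])
        assert [(e.start_s, e.end_s) for e in el] == [(0.0, 4.0), (10.0, 12.0)]

    def test_rejects_inverted_intervals(self):
        with pytest.raises(ValueError):
            EventList([(3.0, 1.0, "seizure")])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0.1, 10)), max_size=8),
           st.randoms())
    def test_construction_is_order_independent(self, raw, rnd):
        events = [Event(s, s + d) for s, d in raw]
        shuffled = list(events)
        rnd.shuffle(shuffled)
        assert EventList(events) == EventList(shuffled)


class TestEdfRoundTrip:
    def test_round_trip_within_16bit_quantization(self, tmp_path):
        rec = _make_recording(CANONICAL_CHANNELS, fs=100.0, dur_s=60.0,
                              events=[Event(5.0, 9.0)])
        path = tmp_path / "rt.edf"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.fs == rec.fs
        assert back.data.shape == (19, 6000)
        # 16-bit quantization step: 2*phys_max/65535 per channel
        step = 2 * np.abs(rec.data).max(axis=1) / 65535
        err = np.abs(back.data - rec.data).max(axis=1)
        assert np.all(err <= step + 1e-9)
        assert len(back.annotations) == 1
        assert back.annotations[0].start_s == pytest.approx(5.0, abs=1e-5)
        assert back.annotations[0].end_s == pytest.approx(9.0, abs=1e-5)

    def test_labels_preserved_verbatim(self, tmp_path):
        labels = ["EEG Fp1-Ref", "EEG FP2-REF"]
        rec = _make_recording(labels)
        path = tmp_path / "labels.edf"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.channel_labels == labels

    def test_internal_dialect_round_trip_is_lossless(self, tmp_path):
        rec = _make_recording(CANONICAL_CHANNELS, events=[Event(1.0, 2.0)])
        path = tmp_path / "rec.h5"
        write_recording(rec, path, dialect="internal")
        back = read_recording(path, dialect="internal")
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.annotations == rec.annotations

    def test_missing_file_and_bad_dialect(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "absent.edf")
        rec = _make_recording(CANONICAL_CHANNELS)
        with pytest.raises(ValueError):
            write_recording(rec, tmp_path / "x.xyz", dialect="xyz")


class TestRecordingInvariants:
    def test_row_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Recording(np.zeros((3, 10)), 100.0, ["a", "b"])

    def test_nonfinite_samples_rejected(self):
        data = np.zeros((1, 10))
        data[0, 3] = np.nan
        with pytest.raises(ValueError):
            Recording(data, 100.0, ["fp1"])

    def test_annotation_beyond_record_end_rejected(self):
        with pytest.raises(ValueError):
            Recording(np.zeros((1, 100)), 100.0, ["fp1"],
                      EventList([Event(0.5, 2.0)]))
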