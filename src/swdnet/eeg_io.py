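"""Reading, writing and normalizing multichannel scalp EEG recordings.

The carrier type :class:`Recording` holds a channels x samples matrix in
microvolts together with its sampling rate, channel labels and seizure
annotations (an :class:`EventList` of ``[start_s, end_s)`` intervals).
Two on-disk dialects are supported: plain EDF (16-bit, written by this
module, read through :mod:`mne`) with a sidecar CSV of annotation
intervals, and an internal HDF5 container used for feature fixtures.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "CANONICAL_CHANNELS",
    "EventList",
    "Recording",
    "canonicalize_label",
    "read_recording",
    "write_recording",
    "select_channels",
    "resample",
    "MissingChannelError",
    "AmbiguousChannelError",
    "FormatError",
]

#: The 19 scalp channels of the reduced 10-20 montage, in the fixed order
#: every downstream stage (feature tensors, network input) assumes.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "fp1", "fp2", "f3", "f4", "c3", "c4", "p3", "p4", "o1", "o2",
    "f7", "f8", "t3", "t4", "t5", "t6", "fz", "cz", "pz",
)

# Modern 10-20 names map onto the legacy temporal names used clinically.
_ALIASES = {"t7": "t3", "t8": "t4", "p7": "t5", "p8": "t6"}

_REF_SUFFIXES = ("-ref", "-le", "-a1", "-a2", "-avg")


class FormatError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


class MissingChannelError(KeyError):
    """Raised when a canonical montage channel cannot be resolved."""


class AmbiguousChannelError(KeyError):
    """Raised when two raw labels resolve to the same canonical channel."""


def canonicalize_label(raw_label: str) -> str | None:
    """Map a raw channel label onto its canonical 10-20 name.

    Case-insensitive; strips an ``"EEG "`` prefix and common reference
    suffixes (``-Ref``, ``-LE``, ...); folds the modern temporal names
    (T7/T8/P7/P8) onto the legacy ones (T3/T4/T5/T6). Returns ``None``
    for anything outside the 19-channel montage (ECG, A1, EMG, ...).
    """
    label = raw_label.strip().lower()
    if label.startswith("eeg "):
        label = label[4:]
    for suffix in _REF_SUFFIXES:
        if label.endswith(suffix):
            label = label[: -len(suffix)]
            break
    label = label.strip()
    label = _ALIASES.get(label, label)
    return label if label in CANONICAL_CHANNELS else None


# ---------------------------------------------------------------------------
# Event lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"event must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "Event") -> float:
        """Length of the intersection with another interval, in seconds."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


class EventList:
    """An ordered, normalized list of ``[start, end)`` intervals in seconds.

    Construction sorts by start time and merges overlapping or touching
    events that share a label, so any permutation of the same intervals
    yields an identical list. Ground truth and predictions share this type.
    """

    def __init__(self, events: Iterable[Event | tuple] = ()) -> None:
        parsed = [e if isinstance(e, Event) else Event(*e) for e in events]
        parsed.sort(key=lambda e: (e.start_s, e.end_s))
        merged: list[Event] = []
        for ev in parsed:
            if merged and ev.label == merged[-1].label and ev.start_s <= merged[-1].end_s:
                last = merged.pop()
                ev = Event(last.start_s, max(last.end_s, ev.end_s), ev.label)
            merged.append(ev)
        self.events: tuple[Event, ...] = tuple(merged)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventList) and self.events == other.events

    def __repr__(self) -> str:
        return f"EventList({list(self.events)!r})"

    @property
    def total_duration_s(self) -> float:
        return sum(e.duration_s for e in self.events)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["start_s", "end_s", "label"])
            for ev in self.events:
                writer.writerow([f"{ev.start_s:.6f}", f"{ev.end_s:.6f}", ev.label])

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventList":
        events = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                events.append(Event(float(row["start_s"]), float(row["end_s"]),
                                    row.get("label", "seizure")))
        return cls(events)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: EventList = field(default_factory=EventList)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite samples")
        for ev in self.annotations:
            if ev.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{ev.start_s}, {ev.end_s}) exceeds record "
                    f"duration {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def select_channels(rec: Recording) -> Recording:
    """Reduce a recording to the 19 canonical channels in fixed order.

    Every canonical name must resolve from exactly one raw label; a missing
    channel raises :class:`MissingChannelError` naming it, and two raw
    labels resolving to the same canonical name raise
    :class:`AmbiguousChannelError` (silent montage mistakes are worse than
    a hard error). Idempotent on already-canonical recordings.
    """
    resolved: dict[str, int] = {}
    for idx, raw in enumerate(rec.channel_labels):
        canon = canonicalize_label(raw)
        if canon is None:
            continue
        if canon in resolved:
            raise AmbiguousChannelError(
                f"labels {rec.channel_labels[resolved[canon]]!r} and {raw!r} "
                f"both resolve to {canon!r}"
            )
        resolved[canon] = idx
    missing = [c for c in CANONICAL_CHANNELS if c not in resolved]
    if missing:
        raise MissingChannelError(f"missing canonical channel(s): {', '.join(missing)}")
    rows = [resolved[c] for c in CANONICAL_CHANNELS]
    return Recording(
        data=rec.data[rows].copy(),
        fs=rec.fs,
        channel_labels=list(CANONICAL_CHANNELS),
        annotations=rec.annotations,
        record_id=rec.record_id,
    )


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling of every channel to ``target_fs``.

    Annotations are in seconds and pass through unchanged. The new sample
    count is ``round(n_samples * target_fs / fs)``.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if abs(target_fs - rec.fs) < 1e-12:
        return Recording(rec.data.copy(), rec.fs, list(rec.channel_labels),
                         rec.annotations, rec.record_id)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    n_target = int(round(rec.n_samples * target_fs / rec.fs))
    if data.shape[1] > n_target:
        data = data[:, :n_target]
    elif data.shape[1] < n_target:
        data = np.pad(data, ((0, 0), (0, n_target - data.shape[1])))
    return Recording(data, float(target_fs), list(rec.channel_labels),
                     rec.annotations, rec.record_id)


# ---------------------------------------------------------------------------
# EDF dialect
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path, dialect: str = "edf") -> None:
    """Write a recording to disk.

    ``edf``: plain EDF, one 1-second data record per second, 16-bit samples
    with per-channel physical scaling; annotations go to a sidecar CSV
    ``<stem>.events.csv`` next to the file. Requires an integer sampling
    rate; a trailing partial second is zero-padded.
    ``internal``: single HDF5 file holding data, fs, labels and events.
    """
    path = Path(path)
    if dialect == "internal":
        _write_internal(rec, path)
        return
    if dialect != "edf":
        raise ValueError(f"unknown dialect {dialect!r}")
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF dialect requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = rec.data
    if rec.n_samples < n_rec * fs:
        data = np.pad(data, ((0, 0), (0, n_rec * fs - rec.n_samples)))

    # Per-channel symmetric physical range; digital range is full int16.
    # Round-trip the range through its 8-char ASCII header field so the
    # writer quantizes with exactly the scale the reader will recover.
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6) * (1 + 1e-6)
    phys_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    dig_min, dig_max = -32768, 32767
    scale = (2 * phys_max) / (dig_max - dig_min)
    digital = np.clip(np.round(data / scale[:, None]), dig_min, dig_max).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.record_id or "X", 80),
        _edf_field("Startdate X swdnet", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    header += b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    rec.annotations.to_csv(_sidecar_path(path))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".events.csv")


def _write_internal(rec: Recording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["record_id"] = rec.record_id
        f.create_dataset("channel_labels",
                         data=np.array(rec.channel_labels, dtype="S16"))
        ev = np.array([(e.start_s, e.end_s) for e in rec.annotations], dtype=np.float64)
        f.create_dataset("events", data=ev.reshape(-1, 2))
        f.create_dataset("event_labels",
                         data=np.array([e.label for e in rec.annotations], dtype="S32"))


def read_recording(path: str | Path, dialect: str = "edf") -> Recording:
    """Read a recording written under the named dialect.

    EDF signals are read through :mod:`mne`; labels are preserved verbatim.
    Annotations come from the embedded EDF+ annotation channel when present,
    otherwise from the sidecar CSV ``<stem>.events.csv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "internal":
        return _read_internal(path)
    if dialect != "edf":
        raise ValueError(f"unknown dialect {dialect!r}")

    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise FormatError(f"{path} contains no channels")
    data = raw.get_data() * 1e6  # mne scales EDF uV channels to volts
    events = []
    for ann in raw.annotations:
        events.append(Event(float(ann["onset"]),
                            float(ann["onset"]) + float(ann["duration"]),
                            str(ann["description"]) or "seizure"))
    sidecar = _sidecar_path(path)
    annotations = EventList(events) if events else (
        EventList.from_csv(sidecar) if sidecar.exists() else EventList()
    )
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=annotations,
        record_id=path.stem,
    )


def _read_internal(path: Path) -> Recording:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs = float(f.attrs["fs"])
            record_id = str(f.attrs["record_id"])
            labels = [s.decode() for s in f["channel_labels"][()]]
            ev = f["events"][()]
            ev_labels = [s.decode() for s in f["event_labels"][()]]
    except OSError as exc:
        raise FormatError(f"cannot parse {path} as internal container: {exc}") from exc
    if data.shape[0] == 0:
        raise FormatError(f"{path} contains no channels")
    events = EventList(Event(a, b, lbl) for (a, b), lbl in zip(ev, ev_labels))
    return Recording(data, fs, labels, events, record_id)
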