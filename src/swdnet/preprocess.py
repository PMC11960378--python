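"""Signal conditioning and feature extraction.

Pipeline order: select the 19 canonical channels, resample to 100 Hz,
band-pass filter (order-12 Butterworth, 0.16-35 Hz, zero-phase by
default), short-time Fourier transform with a Hann taper, assemble the
combined 256-wide feature vector per frame (128 log-magnitude spectrum
bins + 128 decimated raw samples from the same window), normalize per
record, and cut the frame sequence into non-overlapping 64-frame
examples with per-frame seizure labels.

The canonical feature tensor is frames(64) x features(256) x channels(19).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .eeg_io import EventList, Recording, select_channels, resample

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "StftSpec", "FeatureExample",
    "bandpass_filter", "stft_frames", "combined_features",
    "normalize", "make_examples", "preprocess_recording",
    "save_examples", "load_examples",
    "N_FRAMES", "N_FEATURES", "N_CHANNELS",
]

N_FRAMES = 64
N_FEATURES = 256
N_CHANNELS = 19


@dataclass(frozen=True)
class FilterSpec:
    """Order-12 Butterworth band-pass, 0.16-35 Hz.

    ``order`` is the total band-pass order (12 poles, i.e. 6 pole pairs
    per edge). ``application_mode`` "zero-phase" runs the filter forward
    and backward, removing group delay (event boundaries stay put) and
    doubling the effective stop-band attenuation.
    """

    low_cut_hz: float = 0.16
    high_cut_hz: float = 35.0
    order: int = 12
    application_mode: str = "zero-phase"  # or "forward"

    def __post_init__(self) -> None:
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 2 or self.order % 2:
            raise ValueError("band-pass order must be a positive even integer")
        if self.application_mode not in ("forward", "zero-phase"):
            raise ValueError(f"unknown application_mode {self.application_mode!r}")

    def design_sos(self, fs: float) -> np.ndarray:
        """Second-order sections; raises if unstable or fs too low."""
        if self.high_cut_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_cut_hz} Hz requires fs > {2 * self.high_cut_hz} Hz"
            )
        sos = sps.butter(self.order // 2, [self.low_cut_hz, self.high_cut_hz],
                         btype="bandpass", fs=fs, output="sos")
        for section in sos:
            poles = np.roots(section[3:])
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError("unstable filter realization (pole on/outside unit circle)")
        return sos


@dataclass(frozen=True)
class StftSpec:
    """Windowing spec shared by the spectrogram and the raw-signal half.

    ``window_len`` of 256 samples at 100 Hz is the 2.56 s window the
    detector uses; hop defaults to half the window (50% overlap).
    """

    window_len: int = 256
    hop: int = 128
    window_fn: str = "hann"
    n_features: int = N_FEATURES

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be at least 2 samples")
        if self.window_len & (self.window_len - 1):
            raise ValueError("window_len must be a power of two")
        if not (0 < self.hop <= self.window_len):
            raise ValueError("need 0 < hop <= window_len")

    def taper(self) -> np.ndarray:
        if self.window_fn == "rect":
            return np.ones(self.window_len)
        return sps.get_window(self.window_fn, self.window_len, fftbins=True)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_len:
            return 0
        return (n_samples - self.window_len) // self.hop + 1


@dataclass
class FeatureExample:
    """One 64-frame network example.

    ``tensor`` is frames x features x channels = 64 x 256 x 19;
    ``frame_times`` holds each frame's (start_s, end_s) window;
    ``frame_labels`` is 1 where >= 50% of the frame window lies inside a
    seizure event; ``frame_mask`` is False on zero-padded trailing frames
    (excluded from loss and metrics).
    """

    tensor: np.ndarray
    frame_times: np.ndarray
    frame_labels: np.ndarray
    frame_mask: np.ndarray
    source_record: str = ""

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        if self.tensor.shape != (N_FRAMES, N_FEATURES, N_CHANNELS):
            raise ValueError(
                f"tensor must be {N_FRAMES}x{N_FEATURES}x{N_CHANNELS}, "
                f"got {self.tensor.shape}"
            )
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("feature tensor contains non-finite values")


def bandpass_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass filter every channel of a recording.

    Zero-phase mode (default) applies the cascade forward and backward;
    "forward" mode applies a single causal pass.
    """
    sos = spec.design_sos(rec.fs)
    if spec.application_mode == "zero-phase":
        # the 0.16 Hz low cut has a multi-second impulse response; pad by
        # several of its time constants so edge transients die out
        padlen = min(rec.n_samples - 1, int(6 * rec.fs / spec.low_cut_hz))
        data = sps.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    else:
        data = sps.sosfilt(sos, rec.data, axis=1)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     rec.annotations, rec.record_id)


def stft_frames(channel_signal: np.ndarray, spec: StftSpec, fs: float) -> np.ndarray:
    """Short-time Fourier transform of one channel.

    Returns an (n_frames, window_len) complex matrix whose (t, f) entry is
    sum_j x[t*hop + j] * h[j] * exp(-i 2 pi f j / window_len) — the
    discrete windowed DFT, frame t starting at sample t*hop.
    """
    x = np.asarray(channel_signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft_frames expects a single channel vector")
    if len(x) < spec.window_len:
        raise ValueError(
            f"signal length {len(x)} shorter than window {spec.window_len}")
    frames = sliding_window_view(x, spec.window_len)[::spec.hop]
    return np.fft.fft(frames * spec.taper(), axis=1)


def _frame_start_times(n_frames: int, spec: StftSpec, fs: float) -> np.ndarray:
    starts = np.arange(n_frames) * spec.hop / fs
    return np.stack([starts, starts + spec.window_len / fs], axis=1)


def combined_features(rec: Recording, spec: StftSpec = StftSpec()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame combined spectrogram + raw features for all channels.

    Returns ``(features, frame_times)`` with features of shape
    (n_frames, 256, n_channels): positions 0-127 are log(1+|STFT|) of
    frequency bins 0-127 and positions 128-255 are the same 256-sample
    raw window decimated by 2, per the shared window/hop.
    """
    if spec.n_features != N_FEATURES:
        raise ValueError(f"combined feature assembly requires n_features={N_FEATURES}")
    half = N_FEATURES // 2
    nf = spec.n_frames(rec.n_samples)
    out = np.empty((nf, N_FEATURES, rec.n_channels), dtype=np.float32)
    for ch in range(rec.n_channels):
        spec_mat = stft_frames(rec.data[ch], spec, rec.fs)
        out[:, :half, ch] = np.log1p(np.abs(spec_mat[:, :half]))
        raw = sliding_window_view(rec.data[ch], spec.window_len)[::spec.hop]
        out[:, half:, ch] = raw[:, ::2][:, :half]
    return out, _frame_start_times(nf, spec, rec.fs)


def normalize(examples: list[FeatureExample]) -> list[FeatureExample]:
    """Per-record normalization of a FeatureExample stream.

    The raw-signal half of each channel is z-scored over all unmasked
    frames of its source record; the spectrogram half is z-scored with
    the record's global log-magnitude mean and standard deviation (the
    mean subtraction removes the additive offset a device-gain change
    leaves on log magnitudes). Degenerate (constant) channels map to
    zeros and are logged.
    """
    half = N_FEATURES // 2
    by_record: dict[str, list[FeatureExample]] = {}
    for ex in examples:
        by_record.setdefault(ex.source_record, []).append(ex)

    out: list[FeatureExample] = []
    for rid, group in by_record.items():
        stack = np.stack([ex.tensor for ex in group])      # (N,64,256,19)
        mask = np.stack([ex.frame_mask for ex in group])   # (N,64)
        valid = stack[mask]                                # (F,256,19)
        spec_mean = valid[:, :half, :].mean()
        spec_sd = valid[:, :half, :].std()
        if spec_sd < 1e-12:
            logger.warning("record %s: degenerate spectrogram scale, zeroing", rid)
            spec_mean, spec_scale = 0.0, 0.0
        else:
            spec_scale = 1.0 / spec_sd
        raw_mean = valid[:, half:, :].mean(axis=(0, 1))    # per channel
        raw_sd = valid[:, half:, :].std(axis=(0, 1))
        degenerate = raw_sd < 1e-12
        if np.any(degenerate):
            logger.warning("record %s: %d constant channel(s), zeroing",
                           rid, int(degenerate.sum()))
        raw_scale = np.where(degenerate, 0.0, 1.0 / np.where(degenerate, 1.0, raw_sd))
        for ex in group:
            t = ex.tensor.copy()
            t[:, :half, :] = (t[:, :half, :] - spec_mean) * spec_scale
            t[:, half:, :] = (t[:, half:, :] - raw_mean) * raw_scale
            t[~ex.frame_mask] = 0.0
            out.append(FeatureExample(t, ex.frame_times.copy(),
                                      ex.frame_labels.copy(),
                                      ex.frame_mask.copy(), ex.source_record))
    return out


def _label_frames(frame_times: np.ndarray, events: EventList) -> np.ndarray:
    """1 iff >= 50% of the frame's window lies inside a seizure event."""
    labels = np.zeros(len(frame_times), dtype=np.int8)
    for i, (t0, t1) in enumerate(frame_times):
        overlap = 0.0
        for ev in events:
            overlap += max(0.0, min(t1, ev.end_s) - max(t0, ev.start_s))
        if overlap >= 0.5 * (t1 - t0):
            labels[i] = 1
    return labels


def make_examples(rec: Recording, events: EventList | None = None,
                  spec: StftSpec = StftSpec(), apply_normalize: bool = True
                  ) -> list[FeatureExample]:
    """Cut a (filtered, 100 Hz, 19-channel) recording into 64-frame examples.

    Frames within a block overlap per the hop; blocks do not overlap each
    other. The trailing partial block is zero-padded with its padding
    frames masked out of loss and metrics. A record shorter than one
    window yields an empty list with a warning.
    """
    if rec.n_channels != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} canonical channels, got {rec.n_channels}")
    if events is None:
        events = rec.annotations
    if rec.n_samples < spec.window_len:
        warnings.warn(f"record {rec.record_id!r} shorter than one window; no examples",
                      stacklevel=2)
        return []
    feats, times = combined_features(rec, spec)
    labels = _label_frames(times, events)
    nf = feats.shape[0]
    examples = []
    for start in range(0, nf, N_FRAMES):
        block = feats[start : start + N_FRAMES]
        block_t = times[start : start + N_FRAMES]
        block_y = labels[start : start + N_FRAMES]
        n_real = block.shape[0]
        mask = np.zeros(N_FRAMES, dtype=bool)
        mask[:n_real] = True
        if n_real < N_FRAMES:
            pad = N_FRAMES - n_real
            block = np.pad(block, ((0, pad), (0, 0), (0, 0)))
            # keep frame_times strictly increasing through the padding
            extra = _frame_start_times(N_FRAMES, spec, rec.fs)[n_real:] \
                + (block_t[0, 0] if n_real else 0.0)
            block_t = np.concatenate([block_t, extra[: pad]])
            block_y = np.pad(block_y, (0, pad))
        examples.append(FeatureExample(block, block_t, block_y, mask, rec.record_id))
    return normalize(examples) if apply_normalize else examples


def preprocess_recording(rec: Recording,
                         filter_spec: FilterSpec = FilterSpec(),
                         stft_spec: StftSpec = StftSpec(),
                         target_fs: float = 100.0,
                         apply_normalize: bool = True) -> list[FeatureExample]:
    """Full conditioning pipeline: channels -> 100 Hz -> band-pass -> examples."""
    rec = select_channels(rec)
    rec = resample(rec, target_fs)
    rec = bandpass_filter(rec, filter_spec)
    return make_examples(rec, rec.annotations, stft_spec, apply_normalize)


# ---------------------------------------------------------------------------
# Feature container (HDF5)
# ---------------------------------------------------------------------------

def save_examples(examples: list[FeatureExample], path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("examples",
                         data=np.stack([e.tensor for e in examples]).astype(np.float32))
        f.create_dataset("labels", data=np.stack([e.frame_labels for e in examples]))
        f.create_dataset("mask", data=np.stack([e.frame_mask for e in examples]))
        f.create_dataset("frame_times", data=np.stack([e.frame_times for e in examples]))
        f.create_dataset("record_ids",
                         data=np.array([e.source_record for e in examples], dtype="S64"))


def load_examples(path: str | Path) -> list[FeatureExample]:
    import h5py

    with h5py.File(path, "r") as f:
        tensors = f["examples"][()]
        labels = f["labels"][()]
        mask = f["mask"][()]
        times = f["frame_times"][()]
        rids = [s.decode() for s in f["record_ids"][()]]
    return [FeatureExample(t, ft, y, m, r)
            for t, ft, y, m, r in zip(tensors, times, labels, mask, rids)]
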