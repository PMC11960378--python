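"""Synthetic absence-epilepsy EEG generator.

Emulates the statistical structure of clinical absence-seizure EEG so the
whole detection pipeline is testable without patient data: 19-channel
10-20 montage, low-amplitude 1/f background with a posterior-dominant
alpha rhythm, generalized ~3 Hz spike-and-slow-wave bursts with a
frontal/central amplitude maximum, common artifacts (blinks, EMG bursts,
a faint ECG trace), and severe class imbalance (seizure time defaults to
1.08% of the record). This is a phenomenological simulator, not a
neural-mass model: waveform shapes are plausible templates, not fitted.

All randomness flows from the single ``seed`` in :class:`SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .eeg_io import CANONICAL_CHANNELS, Event, EventList, Recording

__all__ = [
    "SynthConfig",
    "ArtifactInterval",
    "generate_background",
    "generate_swd_burst",
    "inject_artifacts",
    "simulate_recording",
    "ConfigurationError",
]

_FRONTAL_CENTRAL = ("fp1", "fp2", "f3", "f4", "fz", "cz")
_POSTERIOR = ("o1", "o2", "p3", "p4")
_TEMPORAL = ("f7", "f8", "t3", "t4", "t5", "t6")

_IDX = {name: i for i, name in enumerate(CANONICAL_CHANNELS)}


class ConfigurationError(ValueError):
    """Raised for infeasible simulation settings."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one simulated corpus.

    ``seizure_fraction`` is the target fraction of record time spent in
    spike-wave discharge (default 0.0108, the clinical corpus imbalance);
    ``swd_freq_hz`` the spike-wave repetition rate; ``frontal_gain`` the
    amplitude multiplier on frontal/central channels; ``noise_scale`` the
    background standard deviation in microvolts.
    """

    duration_s: float = 600.0
    fs: float = 500.0
    n_records: int = 1
    seizure_fraction: float = 0.0108
    swd_freq_hz: float = 3.0
    event_dur_range_s: tuple[float, float] = (4.0, 15.0)
    frontal_gain: float = 1.5
    background_alpha_hz: float = 9.0
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 4.0, "emg": 1.5, "ecg": 1.0}
    )
    noise_scale: float = 15.0
    swd_amp_uv: float = 120.0
    min_event_sep_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.seizure_fraction < 0.5):
            raise ConfigurationError("seizure_fraction must be in [0, 0.5)")
        lo, hi = self.event_dur_range_s
        if not (0 < lo <= hi):
            raise ConfigurationError("event durations must be positive and ordered")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")

    @classmethod
    def balanced(cls, **overrides) -> "SynthConfig":
        """High-seizure-load preset (20% seizure time) for fast CPU training."""
        cfg = cls(seizure_fraction=0.2, **overrides)
        return cfg


class ArtifactInterval(NamedTuple):
    kind: str
    start_s: float
    end_s: float
    channel: str


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_background(config: SynthConfig, n_samples: int,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """19 x n_samples background EEG: 1/f noise + posterior alpha, in uV.

    Spectrally shaped Gaussian noise (power spectral density ~ 1/f above
    0.5 Hz, so band power falls monotonically from 1 to 40 Hz) scaled to
    ``noise_scale`` uV standard deviation per channel, plus an
    amplitude-modulated alpha oscillation concentrated on o1/o2/p3/p4.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if rng is None:
        rng = _rng(config, 1)
    fs = config.fs
    white = rng.standard_normal((19, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shape[0] = 0.0  # zero-mean by construction
    spec = np.fft.rfft(white, axis=1) * shape
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    pink = pink / np.maximum(sd, 1e-12) * config.noise_scale

    # Posterior-dominant alpha with a slow random envelope.
    t = np.arange(n_samples) / fs
    n_env = max(int(config.duration_s) + 2, 4)
    env_knots = 0.5 + 0.5 * rng.random(n_env)
    env = np.interp(t, np.linspace(0, t[-1] if n_samples > 1 else 1.0, n_env), env_knots)
    phase = rng.uniform(0, 2 * np.pi)
    alpha = env * np.sin(2 * np.pi * config.background_alpha_hz * t + phase)
    gains = np.full(19, 0.15)
    for name in _POSTERIOR:
        gains[_IDX[name]] = 1.0
    out = pink + 0.6 * config.noise_scale * gains[:, None] * alpha[None, :]
    return out


def _swd_complex(config: SynthConfig) -> np.ndarray:
    """One spike-and-slow-wave template of one period at ``swd_freq_hz``.

    A sharp positive Gaussian spike (~70 ms wide) followed by a slow
    half-sine (~260 ms), mean-removed; peak normalized to ``swd_amp_uv``.
    """
    fs = config.fs
    period = int(round(fs / config.swd_freq_hz))
    t = np.arange(period) / fs
    spike = np.exp(-0.5 * ((t - 0.05) / 0.012) ** 2)
    slow = np.zeros(period)
    slow_start, slow_dur = 0.09, 0.26
    mask = (t >= slow_start) & (t < slow_start + slow_dur)
    slow[mask] = np.sin(np.pi * (t[mask] - slow_start) / slow_dur)
    wave = spike - 0.65 * slow
    wave -= wave.mean()
    return wave / np.max(np.abs(wave)) * config.swd_amp_uv


def generate_swd_burst(config: SynthConfig, dur_s: float,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """19 x round(dur_s*fs) generalized spike-wave burst, in uV.

    Complexes repeat at ``swd_freq_hz``, synchronous across channels, with
    amplitude multiplied by ``frontal_gain`` on the frontal/central
    channels and mild per-channel variation; a short cosine ramp shapes
    onset and offset.
    """
    lo, hi = config.event_dur_range_s
    if not (lo - 1e-9 <= dur_s <= hi + 1e-9):
        raise ValueError(f"dur_s {dur_s} outside event_dur_range_s {config.event_dur_range_s}")
    if rng is None:
        rng = _rng(config, 2)
    n = int(round(dur_s * config.fs))
    template = _swd_complex(config)
    reps = int(np.ceil(n / len(template)))
    trace = np.tile(template, reps)[:n]

    ramp_n = min(int(0.5 * config.fs), n // 4)
    envelope = np.ones(n)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        envelope[:ramp_n] = ramp
        envelope[-ramp_n:] = ramp[::-1]
    trace = trace * envelope

    gains = np.ones(19)
    for name in _FRONTAL_CENTRAL:
        gains[_IDX[name]] *= config.frontal_gain
    gains *= 1.0 + 0.1 * rng.standard_normal(19)
    gains = np.abs(gains)
    return gains[:, None] * trace[None, :]


def inject_artifacts(background: np.ndarray, config: SynthConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, list[ArtifactInterval]]:
    """Add blink, EMG and ECG contamination; returns (signal, interval log).

    Blinks: ~0.3 s large frontal-dominant deflections. EMG: broadband
    (>20 Hz) bursts on temporal channels. ECG: a faint periodic QRS-like
    trace on all channels. Rates are events per minute; all-zero rates
    return the input unchanged.
    """
    rates = config.artifact_rates or {}
    if all(v == 0 for v in rates.values()):
        return background, []
    if rng is None:
        rng = _rng(config, 3)
    fs = config.fs
    out = background.copy()
    n = out.shape[1]
    dur_min = n / fs / 60.0
    log: list[ArtifactInterval] = []

    t_all = np.arange(n) / fs

    n_blinks = rng.poisson(rates.get("blink", 0.0) * dur_min)
    for _ in range(n_blinks):
        width = 0.3
        center = rng.uniform(width, n / fs - width)
        amp = rng.uniform(80, 150)
        wave = amp * np.exp(-0.5 * ((t_all - center) / (width / 4)) ** 2)
        for name, gain in (("fp1", 1.0), ("fp2", 1.0), ("f3", 0.5),
                           ("f4", 0.5), ("f7", 0.3), ("f8", 0.3)):
            out[_IDX[name]] += gain * wave
            log.append(ArtifactInterval("blink", center - width / 2,
                                        center + width / 2, name))

    n_emg = rng.poisson(rates.get("emg", 0.0) * dur_min)
    for _ in range(n_emg):
        dur = rng.uniform(0.5, 2.0)
        start = rng.uniform(0, max(n / fs - dur, 0))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        if i1 <= i0:
            continue
        burst = rng.standard_normal(i1 - i0)
        # band-limit to 20-80 Hz: genuinely high-frequency muscle activity
        spec = np.fft.rfft(burst)
        f = np.fft.rfftfreq(i1 - i0, 1.0 / fs)
        spec[(f < 20) | (f > 80)] = 0.0
        burst = np.fft.irfft(spec, n=i1 - i0)
        burst *= rng.uniform(50, 90) / max(burst.std(), 1e-12)
        side = rng.choice([0, 1])
        chans = _TEMPORAL[side::2]  # left or right temporal chain
        for name in chans:
            out[_IDX[name], i0:i1] += burst * rng.uniform(0.8, 1.2)
            log.append(ArtifactInterval("emg", start, start + dur, name))

    if rates.get("ecg", 0.0) > 0:
        qrs_period = 1.0 / 1.1  # ~66 bpm
        phase = np.mod(t_all + rng.uniform(0, qrs_period), qrs_period)
        ecg = 4.0 * np.exp(-0.5 * (np.minimum(phase, qrs_period - phase) / 0.02) ** 2)
        out += ecg[None, :]
        log.append(ArtifactInterval("ecg", 0.0, n / fs, "*"))

    return out, log


def _draw_event_plan(config: SynthConfig, rng: np.random.Generator
                     ) -> list[tuple[float, float]]:
    """Choose event durations and non-overlapping start times.

    Durations are drawn uniformly from ``event_dur_range_s`` until their
    sum reaches the target seizure time (the last draw is clipped toward
    the remainder), then placed uniformly at random subject to a
    ``min_event_sep_s`` gap between events and a 1 s margin at the edges.
    """
    lo, hi = config.event_dur_range_s
    target = config.seizure_fraction * config.duration_s
    if target < lo:
        return []
    durations: list[float] = []
    remaining = target
    while remaining >= lo:
        d = rng.uniform(lo, hi)
        d = min(d, max(lo, remaining))
        durations.append(d)
        remaining -= d

    edge = 1.0
    sep = config.min_event_sep_s
    free = config.duration_s - 2 * edge - sum(durations) - sep * (len(durations) - 1)
    if free < 0:
        raise ConfigurationError(
            f"cannot place {sum(durations):.1f} s of events with {sep} s gaps "
            f"in a {config.duration_s} s record"
        )
    cuts = np.sort(rng.uniform(0, free, size=len(durations)))
    events = []
    cursor = edge
    prev_cut = 0.0
    for d, cut in zip(durations, cuts):
        cursor += cut - prev_cut
        events.append((cursor, cursor + d))
        cursor += d + sep
        prev_cut = cut
    return events


def simulate_recording(config: SynthConfig, record_index: int = 0
                       ) -> tuple[Recording, EventList]:
    """Simulate one annotated recording under ``config``.

    Background + artifacts with spike-wave bursts planted at random
    non-overlapping times; the returned :class:`EventList` is the exact
    planted intervals. Total event time lands within the spread of the
    duration-drawing scheme (well inside +/-20% of
    ``seizure_fraction * duration_s`` whenever at least one event fits);
    ``seizure_fraction`` small enough that no event fits yields a pure
    background record with an empty event list. Deterministic in
    ``(seed, record_index)``.
    """
    master = np.random.default_rng(
        np.random.SeedSequence((config.seed, 100 + record_index)))
    streams = master.spawn(4)
    plan = _draw_event_plan(config, streams[2])  # fail fast if infeasible
    n = int(round(config.duration_s * config.fs))
    data = generate_background(config, n, rng=streams[0])
    data, _ = inject_artifacts(data, config, rng=streams[1])
    burst_rng = streams[3]
    for start_s, end_s in plan:
        burst = generate_swd_burst(config, end_s - start_s, rng=burst_rng)
        i0 = int(round(start_s * config.fs))
        data[:, i0 : i0 + burst.shape[1]] += burst

    events = EventList(Event(s, e, "seizure") for s, e in plan)
    rec = Recording(
        data=data,
        fs=config.fs,
        channel_labels=list(CANONICAL_CHANNELS),
        annotations=events,
        record_id=f"synth-{config.seed:05d}-{record_index:03d}",
    )
    return rec, events


def simulate_corpus(config: SynthConfig) -> list[tuple[Recording, EventList]]:
    """Simulate ``config.n_records`` independent recordings."""
    return [simulate_recording(config, i) for i in range(config.n_records)]
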