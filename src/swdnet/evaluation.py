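"""Event-based seizure scoring.

Per-frame probabilities are decoded into predicted seizure intervals
(threshold, merge nearby runs, drop very short ones); predictions are
matched to ground truth one-to-one by temporal overlap — a true event
counts as detected (TP) when a predicted event overlaps it by more than
2 seconds. True negatives, which event lists do not define naturally,
are counted as 10 s background windows free of any prediction; the
window size is echoed in every report. The five headline metrics are
TPR (sensitivity), TNR (specificity), PPV, NPV and F1 (the harmonic
mean of TPR and PPV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eeg_io import Event, EventList

__all__ = [
    "EvalReport", "probs_to_events", "match_events",
    "count_true_negatives", "compute_metrics", "evaluate_events",
]

UNDEFINED = None  # metrics with a zero denominator carry this flag


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else UNDEFINED


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float | None = field(init=False)
    tnr: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    f1: float | None = field(init=False)
    matched_pairs: list[tuple[Event, Event, float]] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        self.tpr = _safe_ratio(self.tp, self.tp + self.fn)
        self.tnr = _safe_ratio(self.tn, self.tn + self.fp)
        self.ppv = _safe_ratio(self.tp, self.tp + self.fp)
        self.npv = _safe_ratio(self.tn, self.tn + self.fn)
        if self.tpr is not None and self.ppv is not None and (self.tpr + self.ppv) > 0:
            self.f1 = 2 * self.tpr * self.ppv / (self.tpr + self.ppv)
        elif self.tpr is not None and self.ppv is not None:
            self.f1 = 0.0
        else:
            self.f1 = UNDEFINED

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "tnr": self.tnr, "ppv": self.ppv,
            "npv": self.npv, "f1": self.f1,
            "matched_pairs": [
                {"truth": [t.start_s, t.end_s], "predicted": [p.start_s, p.end_s],
                 "overlap_s": o}
                for t, p, o in self.matched_pairs
            ],
            "config_echo": self.config_echo,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """TPR/TNR/PPV/NPV/F1 from confusion counts; zero denominators are
    flagged undefined (None), never a division error."""
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)


def probs_to_events(frame_probs: np.ndarray, frame_times: np.ndarray,
                    threshold: float = 0.5, merge_gap_s: float = 1.0,
                    min_dur_s: float = 1.0) -> EventList:
    """Decode per-frame probabilities into predicted seizure intervals.

    Frames at or above ``threshold`` form maximal runs; a run spans from
    its first frame's window start to its last frame's window end. Runs
    closer than ``merge_gap_s`` are merged, then intervals shorter than
    ``min_dur_s`` are dropped.
    """
    probs = np.asarray(frame_probs, dtype=float).ravel()
    times = np.asarray(frame_times, dtype=float).reshape(-1, 2)
    if len(probs) != len(times):
        raise ValueError("frame_probs and frame_times lengths differ")
    if np.any(np.diff(times[:, 0]) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    hot = probs >= threshold
    intervals: list[list[float]] = []
    prev_idx = -2
    for i in np.flatnonzero(hot):
        if i == prev_idx + 1:
            intervals[-1][1] = max(intervals[-1][1], times[i, 1])
        else:
            intervals.append([times[i, 0], times[i, 1]])
        prev_idx = i
    merged: list[list[float]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return EventList(Event(s, e, "seizure") for s, e in merged
                     if e - s >= min_dur_s)


def match_events(predicted: EventList, truth: EventList,
                 min_overlap_s: float = 2.0
                 ) -> tuple[int, int, int, list[tuple[Event, Event, float]]]:
    """Greedy one-to-one matching in time order by the >2 s overlap rule.

    Returns (tp, fp, fn, matched_pairs). A true event is a TP iff some
    not-yet-matched predicted event overlaps it by more than
    ``min_overlap_s``; remaining truth is FN, remaining predictions FP.
    """
    used = [False] * len(predicted)
    pairs: list[tuple[Event, Event, float]] = []
    tp = 0
    for t_ev in truth:
        for j, p_ev in enumerate(predicted):
            if used[j]:
                continue
            ov = t_ev.overlap_s(p_ev)
            if ov > min_overlap_s:
                used[j] = True
                pairs.append((t_ev, p_ev, ov))
                tp += 1
                break
    fn = len(truth) - tp
    fp = used.count(False)
    return tp, fp, fn, pairs


def count_true_negatives(truth: EventList, predicted: EventList,
                         record_dur_s: float, tn_window_s: float = 10.0) -> int:
    """Count seizure-free windows the detector also left clean.

    The background (complement of true events) is tiled into
    non-overlapping ``tn_window_s`` windows; a window is a TN iff no
    predicted event intersects it.
    """
    if record_dur_s < 0:
        raise ValueError("record_dur_s must be >= 0")
    tn = 0
    cursor = 0.0
    background: list[tuple[float, float]] = []
    for ev in truth:
        if ev.start_s > cursor:
            background.append((cursor, min(ev.start_s, record_dur_s)))
        cursor = max(cursor, ev.end_s)
    if cursor < record_dur_s:
        background.append((cursor, record_dur_s))
    for b0, b1 in background:
        n_windows = int((b1 - b0) / tn_window_s)
        for k in range(n_windows):
            w0 = b0 + k * tn_window_s
            w1 = w0 + tn_window_s
            if not any(min(w1, p.end_s) - max(w0, p.start_s) > 0 for p in predicted):
                tn += 1
    return tn


def evaluate_events(predicted: EventList, truth: EventList,
                    record_dur_s: float, min_overlap_s: float = 2.0,
                    tn_window_s: float = 10.0) -> EvalReport:
    """Full event-level evaluation of one record (or a pooled corpus)."""
    tp, fp, fn, pairs = match_events(predicted, truth, min_overlap_s)
    tn = count_true_negatives(truth, predicted, record_dur_s, tn_window_s)
    report = compute_metrics(tp, fp, tn, fn)
    report.matched_pairs = pairs
    report.config_echo = {"min_overlap_s": min_overlap_s,
                          "tn_window_s": tn_window_s}
    return report


def detect_recording(model, rec, filter_spec=None, stft_spec=None,
                     threshold: float = 0.5, merge_gap_s: float = 1.0,
                     min_dur_s: float = 1.0) -> tuple[EventList, np.ndarray, np.ndarray]:
    """Run the full detector on one raw recording.

    Preprocesses (channel selection, 100 Hz, band-pass, features), runs
    the model, and decodes frame probabilities into predicted events.
    Returns (events, frame_probs, frame_times) over all real frames.
    """
    from .preprocess import FilterSpec, StftSpec, preprocess_recording
    from .training import predict_probs

    filter_spec = filter_spec or FilterSpec()
    stft_spec = stft_spec or StftSpec()
    examples = preprocess_recording(rec, filter_spec, stft_spec)
    if not examples:
        return EventList(), np.empty(0), np.empty((0, 2))
    probs = predict_probs(model, examples)
    flat_p, flat_t = [], []
    for ex, p in zip(examples, probs):
        flat_p.append(p[ex.frame_mask])
        flat_t.append(ex.frame_times[ex.frame_mask])
    frame_probs = np.concatenate(flat_p)
    frame_times = np.concatenate(flat_t)
    events = probs_to_events(frame_probs, frame_times, threshold,
                             merge_gap_s, min_dur_s)
    return events, frame_probs, frame_times


def pool_reports(reports: list[EvalReport]) -> EvalReport:
    """Micro-average: sum confusion counts across records, recompute metrics."""
    rep = compute_metrics(sum(r.tp for r in reports), sum(r.fp for r in reports),
                          sum(r.tn for r in reports), sum(r.fn for r in reports))
    rep.config_echo = reports[0].config_echo if reports else {}
    return rep
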