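"""Voice-dosimetry scoring and reporting.

Given a per-frame decision track (and optionally ground truth), this module
computes the quantities a phonation-monitoring session reports:

* frame-level accuracy (overall agreement, plus recall and precision on the
  speech class, with the raw counts);
* the phonation ratio — speech frames / total frames — both overall and as
  a trajectory over time (cumulative or sliding window);
* the decomposition of the track into alternating speech/nonspeech
  segments and their duration distribution on log-spaced bins.

Percentages are conventionally reported to one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import FrameGrid, LabelTrack
from .envelope_detector import DecisionTrack

__all__ = [
    "Segment",
    "AccuracySummary",
    "PhonationReport",
    "frame_accuracy",
    "phonation_ratio",
    "ratio_over_time",
    "to_segments",
    "duration_histogram",
    "default_log_bins",
    "build_report",
    "track_to_labels",
]


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    kind: str  # "speech" | "nonspeech"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} must exceed start {self.start}")
        if self.kind not in ("speech", "nonspeech"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AccuracySummary:
    """Frame-agreement scores of predictions against ground truth."""

    agreement: float
    recall: float
    precision: float
    n_correct: int
    n_total: int
    n_true_speech: int
    n_pred_speech: int
    n_speech_correct: int

    def as_dict(self) -> dict:
        return {
            "agreement": self.agreement,
            "agreement_pct": round(100.0 * self.agreement, 1),
            "recall": self.recall,
            "precision": self.precision,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "n_true_speech": self.n_true_speech,
            "n_pred_speech": self.n_pred_speech,
            "n_speech_correct": self.n_speech_correct,
        }


@dataclass
class PhonationReport:
    overall_ratio: float
    ratio_times: np.ndarray
    ratio_values: np.ndarray
    segments: list[Segment]
    histogram_edges: np.ndarray
    histogram: dict[str, np.ndarray]  # kind -> counts (last bin = overflow)
    accuracy: AccuracySummary | None = None
    extras: dict = field(default_factory=dict)


def frame_accuracy(pred: DecisionTrack | np.ndarray, truth: np.ndarray) -> AccuracySummary:
    """Score predicted frames against ground truth.

    ``agreement`` counts both classes; ``recall`` is correctly predicted
    speech frames over true speech frames; ``precision`` the analog over
    predicted speech frames.  Empty classes yield 0 for the affected rate.
    """
    p = np.asarray(pred.decisions if isinstance(pred, DecisionTrack) else pred)
    t = np.asarray(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truth")
    if len(p) == 0:
        raise ValueError("cannot score empty tracks")
    p, t = p.astype(bool), t.astype(bool)
    n_correct = int(np.sum(p == t))
    n_speech_correct = int(np.sum(p & t))
    n_true = int(t.sum())
    n_pred = int(p.sum())
    return AccuracySummary(
        agreement=n_correct / len(p),
        recall=n_speech_correct / n_true if n_true else 0.0,
        precision=n_speech_correct / n_pred if n_pred else 0.0,
        n_correct=n_correct,
        n_total=len(p),
        n_true_speech=n_true,
        n_pred_speech=n_pred,
        n_speech_correct=n_speech_correct,
    )


def phonation_ratio(track: DecisionTrack | np.ndarray) -> float:
    """Fraction of frames classified as speech."""
    d = np.asarray(track.decisions if isinstance(track, DecisionTrack) else track)
    if len(d) == 0:
        raise ValueError("cannot compute phonation ratio of an empty track")
    return float(np.mean(d != 0))


def ratio_over_time(
    track: DecisionTrack, mode: str = "sliding", window: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Phonation-ratio trajectory: one (time, ratio) point per frame.

    ``cumulative`` reports the ratio over [0, t]; ``sliding`` over
    [t - window, t] (truncated at the start).  Times are frame end times.
    """
    d = track.decisions.astype(np.float64)
    n = len(d)
    if n == 0:
        raise ValueError("empty track")
    hop = track.grid.hop
    times = (np.arange(n) + 1) * hop
    csum = np.cumsum(d)
    if mode == "cumulative":
        ratios = csum / np.arange(1, n + 1)
    elif mode == "sliding":
        w = int(round(window / hop))
        if w < 1:
            raise ValueError(f"window {window}s shorter than one frame ({hop}s)")
        padded = np.concatenate(([0.0], csum))
        lo = np.maximum(np.arange(1, n + 1) - w, 0)
        counts = np.arange(1, n + 1) - lo
        ratios = (padded[1:] - padded[lo]) / counts
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'cumulative' or 'sliding'")
    return times, ratios


def to_segments(track: DecisionTrack) -> list[Segment]:
    """Run-length decomposition into alternating speech/nonspeech segments.

    Segment times are multiples of the hop; segments tile [0, n_frames*hop]
    without gaps.
    """
    d = track.decisions
    if len(d) == 0:
        raise ValueError("empty track")
    hop = track.grid.hop
    changes = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [len(d)]))
    return [
        Segment(
            start=float(s * hop),
            end=float(e * hop),
            kind="speech" if d[s] else "nonspeech",
        )
        for s, e in zip(starts, ends)
    ]


def default_log_bins(
    lo: float = 0.032, hi: float = 1000.0, per_decade: int = 10
) -> np.ndarray:
    """Log-spaced duration-bin edges (seconds), ~``per_decade`` bins/decade."""
    n_bins = int(np.ceil(per_decade * np.log10(hi / lo)))
    return np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)


def duration_histogram(
    segments: list[Segment], bins: np.ndarray | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Count segment durations per kind on left-closed right-open bins.

    Returns ``(edges, counts_by_kind)`` where each counts array has
    ``len(edges)`` entries: ``len(edges) - 1`` in-range bins plus a final
    overflow bin for durations outside [edges[0], edges[-1]).
    """
    edges = default_log_bins() if bins is None else np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts = {
        kind: np.zeros(len(edges), dtype=int) for kind in ("speech", "nonspeech")
    }
    for seg in segments:
        c = counts[seg.kind]
        if edges[0] <= seg.duration < edges[-1]:
            c[np.searchsorted(edges, seg.duration, side="right") - 1] += 1
        else:
            c[-1] += 1  # overflow bin
    return edges, counts


def track_to_labels(track: DecisionTrack) -> LabelTrack:
    """Export speech segments of a decision track as a label track."""
    intervals = tuple(
        (seg.start, min(seg.end, track.grid.duration))
        for seg in to_segments(track)
        if seg.kind == "speech" and seg.start < track.grid.duration
    )
    return LabelTrack(intervals=intervals, total_duration=track.grid.duration)


def build_report(
    track: DecisionTrack,
    truth: np.ndarray | None = None,
    ratio_mode: str = "sliding",
    ratio_window: float = 60.0,
    bins: np.ndarray | None = None,
) -> PhonationReport:
    """Assemble the full dosimetry report for one session."""
    times, ratios = ratio_over_time(track, mode=ratio_mode, window=ratio_window)
    segments = to_segments(track)
    edges, counts = duration_histogram(segments, bins)
    return PhonationReport(
        overall_ratio=phonation_ratio(track),
        ratio_times=times,
        ratio_values=ratios,
        segments=segments,
        histogram_edges=edges,
        histogram=counts,
        accuracy=frame_accuracy(track, truth) if truth is not None else None,
    )
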