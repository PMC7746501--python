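"""Audio and label-track I/O plus frame-grid bookkeeping.

The detector operates on 16 kHz mono audio cut into fixed-length analysis
frames (32 ms by default, non-overlapping).  This module owns the three
carrier types — :class:`AudioSignal`, :class:`LabelTrack` and
:class:`FrameGrid` — and the conversions between continuous-time speech
annotations and per-frame binary label sequences.

Label files use the Audacity-style tab-separated dialect::

    start_seconds<TAB>end_seconds<TAB>label

with ``label`` either ``speech`` or ``nonspeech``; nonspeech lines are
optional and ignored on read (nonspeech is the complement of speech).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_RATE = 16_000
DEFAULT_FRAME_SEC = 0.032

__all__ = [
    "AudioSignal",
    "LabelTrack",
    "FrameGrid",
    "AudioIOError",
    "LabelFormatError",
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "labels_to_frames",
    "frames_to_labels",
]


class AudioIOError(ValueError):
    """Unreadable, corrupt, or empty audio input."""


class LabelFormatError(ValueError):
    """Malformed label-track file."""


@dataclass(frozen=True)
class AudioSignal:
    """Single-channel audio: amplitude samples in [-1, 1] plus a sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioIOError("AudioSignal must be single-channel (1-D)")
        if not np.all(np.isfinite(samples)):
            raise AudioIOError("AudioSignal contains non-finite samples")
        if self.rate <= 0:
            raise AudioIOError(f"sample rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class LabelTrack:
    """Sorted, non-overlapping speech intervals over a recording."""

    intervals: tuple[tuple[float, float], ...]
    total_duration: float

    def __post_init__(self) -> None:
        ivs = tuple((float(s), float(e)) for s, e in self.intervals)
        prev_end = 0.0
        for s, e in ivs:
            if not (0.0 <= s < e <= self.total_duration + 1e-9):
                raise LabelFormatError(
                    f"interval ({s}, {e}) outside [0, {self.total_duration}]"
                )
            if s < prev_end - 1e-12:
                raise LabelFormatError("intervals must be sorted and non-overlapping")
            prev_end = e
        object.__setattr__(self, "intervals", ivs)

    @property
    def speech_seconds(self) -> float:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class FrameGrid:
    """Uniform analysis-frame timing over a signal of known duration.

    ``n_frames = floor((duration - frame_length)/hop) + 1``; frames are
    non-overlapping by default (hop == frame length, 512 samples at 16 kHz).
    """

    duration: float
    frame_length: float = DEFAULT_FRAME_SEC
    hop: float = DEFAULT_FRAME_SEC
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.frame_length <= 0:
            raise ValueError("frame_length must be positive")
        if not (0 < self.hop <= self.frame_length):
            raise ValueError("hop must satisfy 0 < hop <= frame_length")

    @property
    def n_frames(self) -> int:
        n = math.floor((self.duration - self.frame_length) / self.hop + 1e-9) + 1
        return max(n, 0)

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_length * self.rate))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop * self.rate))

    def frame_center(self, j: int | np.ndarray) -> float | np.ndarray:
        """Center time (seconds) of frame ``j``."""
        return j * self.hop + self.frame_length / 2.0

    @classmethod
    def for_signal(
        cls,
        signal: AudioSignal,
        frame_length: float = DEFAULT_FRAME_SEC,
        hop: float | None = None,
    ) -> "FrameGrid":
        return cls(
            duration=signal.duration,
            frame_length=frame_length,
            hop=frame_length if hop is None else hop,
            rate=signal.rate,
        )


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path, target_rate: int = DEFAULT_RATE) -> AudioSignal:
    """Read a PCM/float WAV file as mono float audio at ``target_rate``.

    Multi-channel input is averaged across channels.  Integer PCM is scaled
    to [-1, 1]; amplitude is otherwise preserved (no peak normalization).
    Resampling uses a polyphase filter.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises assorted ValueError subtypes
        raise AudioIOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioIOError(f"WAV file {path} contains no audio")

    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM (16/32-bit)
            samples = data.astype(np.float64) / float(-info.min)
        else:  # 8-bit unsigned PCM, midpoint 128
            samples = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        samples = data.astype(np.float64)

    if samples.ndim == 2:
        samples = samples.mean(axis=1)

    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    return AudioSignal(samples=samples, rate=target_rate)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write audio as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), signal.rate, pcm)


# ---------------------------------------------------------------------------
# Label-track I/O
# ---------------------------------------------------------------------------

def _merge_intervals(
    intervals: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_labels(path: str | Path, total_duration: float) -> LabelTrack:
    """Parse a tab-separated label file into a :class:`LabelTrack`.

    Lines are ``start<TAB>end<TAB>label``.  Only ``speech`` lines contribute
    intervals; overlapping speech intervals are merged and everything is
    clipped to ``[0, total_duration]``.
    """
    path = Path(path)
    intervals: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()  # tolerate space-separated hand edits
            if len(parts) < 3:
                raise LabelFormatError(
                    f"{path}:{lineno}: expected 'start<TAB>end<TAB>label'"
                )
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelFormatError(
                    f"{path}:{lineno}: non-numeric start/end field"
                ) from exc
            if end <= start:
                raise LabelFormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            label = parts[2].lower()
            if label != "speech":
                continue
            start = max(start, 0.0)
            end = min(end, total_duration)
            if end > start:
                intervals.append((start, end))
    return LabelTrack(
        intervals=tuple(_merge_intervals(intervals)), total_duration=total_duration
    )


def write_labels(path: str | Path, labels: LabelTrack) -> None:
    """Write speech intervals in the label-TSV dialect (3 decimal places min)."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for s, e in labels.intervals:
            fh.write(f"{s:.6f}\t{e:.6f}\tspeech\n")


# ---------------------------------------------------------------------------
# Labels <-> frames
# ---------------------------------------------------------------------------

def labels_to_frames(labels: LabelTrack, grid: FrameGrid) -> np.ndarray:
    """Per-frame binary ground truth: 1 iff the frame center is inside speech."""
    n = grid.n_frames
    out = np.zeros(n, dtype=np.int8)
    if n == 0 or not labels.intervals:
        return out
    centers = grid.frame_center(np.arange(n))
    starts = np.array([s for s, _ in labels.intervals])
    ends = np.array([e for _, e in labels.intervals])
    # index of the first interval whose start is > center, minus one
    idx = np.searchsorted(starts, centers, side="right") - 1
    valid = idx >= 0
    out[valid] = (centers[valid] < ends[idx[valid]]).astype(np.int8)
    return out


def frames_to_labels(frames: np.ndarray, grid: FrameGrid) -> LabelTrack:
    """Inverse of :func:`labels_to_frames` up to one hop of quantization.

    Maximal runs of 1-frames become speech intervals spanning from the start
    of the first frame in the run to the end of the last.
    """
    frames = np.asarray(frames)
    intervals: list[tuple[float, float]] = []
    if frames.size:
        padded = np.concatenate(([0], frames.astype(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        for a, b in zip(edges[::2], edges[1::2]):
            start = a * grid.hop
            end = (b - 1) * grid.hop + grid.frame_length
            intervals.append((start, min(end, grid.duration)))
    return LabelTrack(
        intervals=tuple(_merge_intervals(intervals)), total_duration=grid.duration
    )
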