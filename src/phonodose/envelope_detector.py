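"""Energy-envelope extraction and the adaptive-threshold (AT) decision rule.

The detector classifies each 32 ms frame as speech or nonspeech by comparing
the frame's power energy E_j against a threshold computed from the current
and three preceding frame energies:

    AT_j = a_0*E_j + a_1*E_{j-1} + a_2*E_{j-2} + a_3*E_{j-3} + b

Frame j is speech iff E_j > AT_j (strict; ties resolve to nonspeech).
Energies before the start of the signal are taken as zero, so the decision
track always has exactly one entry per frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_io import AudioSignal, FrameGrid

N_LAGS = 4  # current frame + 3 preceding

__all__ = [
    "EnvelopeSeries",
    "ATCoefficients",
    "DecisionTrack",
    "compute_envelope",
    "lag_matrix",
    "adaptive_threshold",
    "detect",
    "run_pipeline",
    "median_smooth",
]


@dataclass(frozen=True)
class EnvelopeSeries:
    """Per-frame power energies (non-negative) on a frame grid."""

    values: np.ndarray
    grid: FrameGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if np.any(values < 0):
            raise ValueError("envelope energies must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ATCoefficients:
    """The five fitted parameters of the adaptive threshold.

    ``a`` holds (a_0, a_1, a_2, a_3): a_0 weights the current frame, a_1..a_3
    the three preceding frames.  ``b`` is the bias, in energy units (mean
    squared amplitude), which sets the floor of the threshold.
    """

    a: tuple[float, float, float, float]
    b: float

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.a)
        if len(a) != N_LAGS:
            raise ValueError(f"expected {N_LAGS} envelope coefficients, got {len(a)}")
        if not all(np.isfinite(a)) or not np.isfinite(self.b):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", float(self.b))

    def as_vector(self) -> np.ndarray:
        """(a_0, a_1, a_2, a_3, b) as a length-5 array."""
        return np.array([*self.a, self.b])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ATCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_LAGS + 1,):
            raise ValueError("coefficient vector must have 5 entries")
        return cls(a=tuple(vec[:N_LAGS]), b=float(vec[N_LAGS]))

    def save(self, path: str | Path, grid: "FrameGrid | None" = None) -> None:
        """Write the flat key-value coefficient file (a0..a3, b), optionally
        with the frame-grid metadata the fit used."""
        with open(Path(path), "w", encoding="utf-8") as fh:
            for i, val in enumerate(self.a):
                fh.write(f"a{i} = {val!r}\n")
            fh.write(f"b = {self.b!r}\n")
            if grid is not None:
                fh.write(f"frame_length = {grid.frame_length!r}\n")
                fh.write(f"hop = {grid.hop!r}\n")
                fh.write(f"rate = {grid.rate}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ATCoefficients":
        kv: dict[str, float] = {}
        with open(Path(path), encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = float(val.strip())
        try:
            return cls(a=tuple(kv[f"a{i}"] for i in range(N_LAGS)), b=kv["b"])
        except KeyError as exc:
            raise ValueError(f"coefficient file {path} missing key {exc}") from exc


@dataclass(frozen=True)
class DecisionTrack:
    """Per-frame binary speech (1) / nonspeech (0) decisions."""

    decisions: np.ndarray
    grid: FrameGrid

    def __post_init__(self) -> None:
        d = np.asarray(self.decisions)
        if not np.isin(d, (0, 1)).all():
            raise ValueError("decisions must be binary")
        object.__setattr__(self, "decisions", d.astype(np.int8))

    def __len__(self) -> int:
        return len(self.decisions)


def compute_envelope(signal: AudioSignal, grid: FrameGrid | None = None) -> EnvelopeSeries:
    """Per-frame power energy: mean squared amplitude, rectangular window."""
    if grid is None:
        grid = FrameGrid.for_signal(signal)
    n = grid.n_frames
    if n == 0:
        raise ValueError(
            f"signal ({signal.duration:.4f} s) shorter than one frame "
            f"({grid.frame_length} s)"
        )
    flen, hop = grid.frame_samples, grid.hop_samples
    idx = np.arange(n)[:, None] * hop + np.arange(flen)[None, :]
    frames = signal.samples[idx]
    return EnvelopeSeries(values=(frames * frames).mean(axis=1), grid=grid)


def lag_matrix(values: np.ndarray, include_current: bool = True) -> np.ndarray:
    """Stack (E_j, E_{j-1}, E_{j-2}, E_{j-3}) row-wise with zero warm-up.

    With ``include_current=False`` the first column is zeroed, excluding the
    current frame's energy from the threshold sum.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    lags = np.zeros((n, N_LAGS))
    for i in range(N_LAGS):
        lags[i:, i] = values[: n - i]
    if not include_current:
        lags[:, 0] = 0.0
    return lags


def adaptive_threshold(
    env: EnvelopeSeries,
    coef: ATCoefficients,
    j: int | None = None,
    include_current: bool = True,
) -> float | np.ndarray:
    """Threshold AT_j; with ``j=None`` the full per-frame threshold series."""
    thresholds = lag_matrix(env.values, include_current) @ np.array(coef.a) + coef.b
    if j is None:
        return thresholds
    if not 0 <= j < len(env):
        raise IndexError(f"frame index {j} out of range [0, {len(env)})")
    return float(thresholds[j])


def detect(
    env: EnvelopeSeries, coef: ATCoefficients, include_current: bool = True
) -> DecisionTrack:
    """Speech decision per frame: 1 iff E_j strictly exceeds AT_j."""
    if len(env) == 0:
        raise ValueError("cannot detect on an empty envelope")
    at = adaptive_threshold(env, coef, include_current=include_current)
    return DecisionTrack(decisions=(env.values > at).astype(np.int8), grid=env.grid)


def median_smooth(track: DecisionTrack, window: int) -> DecisionTrack:
    """Optional post-process: odd-window median filter over decisions."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be a positive odd integer")
    if window == 1:
        return track
    from scipy.signal import medfilt

    smoothed = medfilt(track.decisions.astype(float), kernel_size=window)
    return DecisionTrack(decisions=smoothed.astype(np.int8), grid=track.grid)


def run_pipeline(
    signal: AudioSignal,
    coef: ATCoefficients,
    grid: FrameGrid | None = None,
    denoise: bool = False,
    nr_params=None,
    include_current: bool = True,
    smooth_window: int = 1,
) -> DecisionTrack:
    """Full detection chain: (optional logMMSE enhancement) -> envelope -> AT.

    With ``denoise`` on, the signal is first enhanced and the envelope is
    computed on the enhanced signal; otherwise the raw signal is framed
    directly.
    """
    if denoise:
        from .noise_lab import NRParams, logmmse

        signal = logmmse(signal, nr_params if nr_params is not None else NRParams())
    if grid is None:
        grid = FrameGrid.for_signal(signal)
    env = compute_envelope(signal, grid)
    track = detect(env, coef, include_current=include_current)
    if smooth_window > 1:
        track = median_smooth(track, smooth_window)
    return track
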