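"""Noise mixing at calibrated SNR and logMMSE speech enhancement.

Three responsibilities:

* :func:`mix_at_snr` — add background noise to a clean recording so the
  whole-signal SNR equals the requested value exactly (by construction).
* :func:`make_noise` — seed-reproducible generators for four background
  noise archetypes: white (Gaussian), street (low-frequency rumble with slow
  level drift), sharp_speech (sparse abrupt speech-band bursts), and crowd
  (babble: a superposition of independent speech-like harmonic streams).
* :func:`logmmse` — the log-spectral-amplitude MMSE enhancer: STFT
  analysis/overlap-add synthesis, noise-PSD tracking with a
  likelihood-ratio speech-absence test, decision-directed a-priori SNR
  estimation, and the gain G = (xi/(1+xi)) * exp(E1(v)/2) with
  v = xi*gamma/(1+xi), floored at ``gain_floor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt
from scipy.special import exp1

from .audio_io import AudioSignal

__all__ = ["NoiseSpec", "NRParams", "mix_at_snr", "logmmse", "make_noise", "NOISE_KINDS"]

NOISE_KINDS = ("white", "street", "sharp_speech", "crowd")


@dataclass(frozen=True)
class NoiseSpec:
    """A noise condition: archetype name (or WAV path) plus target SNR in dB."""

    kind: str
    snr_db: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass(frozen=True)
class NRParams:
    """logMMSE tuning parameters (defaults follow common published practice)."""

    fft_frame: float = 0.032      # analysis frame length, seconds (Hann window)
    overlap: float = 0.5          # fractional frame overlap
    noise_init_frames: int = 6    # frames assumed speech-absent at start
    alpha_dd: float = 0.98        # decision-directed smoothing
    xi_min_db: float = -25.0      # a-priori SNR floor
    gain_floor: float = 0.1       # minimum spectral gain
    noise_smooth: float = 0.98    # noise-PSD update smoothing in absent frames
    vad_threshold: float = 0.05   # mean log-likelihood ratio below -> absent

    def __post_init__(self) -> None:
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if not 0 <= self.alpha_dd < 1:
            raise ValueError("alpha_dd must be in [0, 1)")
        if not 0 < self.gain_floor <= 1:
            raise ValueError("gain_floor must be in (0, 1]")
        if self.noise_init_frames < 1:
            raise ValueError("noise_init_frames must be >= 1")


def mix_at_snr(
    clean: AudioSignal,
    noise: AudioSignal,
    snr_db: float,
    seed: int = 0,
    active_labels=None,
) -> AudioSignal:
    """Scale and add noise so the whole-signal SNR equals ``snr_db`` exactly.

    The gain is g = sqrt(P_clean / (P_noise * 10^(snr/10))) with P the mean
    power of each signal over the aligned span.  A noise track shorter than
    the speech is looped; a longer one is cropped at a seed-chosen offset.

    With ``active_labels`` (a speech-interval LabelTrack) the clean power is
    measured over labeled speech samples only, so the SNR refers to the
    speech-active portion rather than the whole recording.
    """
    if clean.rate != noise.rate:
        raise ValueError(f"rate mismatch: clean {clean.rate} vs noise {noise.rate}")
    n = len(clean)
    rng = np.random.default_rng(seed)
    noise_samples = noise.samples
    if len(noise_samples) < n:
        reps = int(np.ceil(n / len(noise_samples)))
        noise_samples = np.tile(noise_samples, reps)
    offset = int(rng.integers(0, len(noise_samples) - n + 1))
    segment = noise_samples[offset:offset + n]

    if active_labels is not None:
        mask = np.zeros(n, dtype=bool)
        for s, e in active_labels.intervals:
            mask[int(s * clean.rate):int(e * clean.rate)] = True
        if not mask.any():
            raise ValueError("active-SNR mixing requires at least one speech interval")
        p_clean = float(np.mean(clean.samples[mask] ** 2))
    else:
        p_clean = float(np.mean(clean.samples**2))
    p_noise = float(np.mean(segment**2))
    if p_clean == 0.0 or p_noise == 0.0:
        raise ValueError("SNR undefined: clean or noise signal has zero power")
    gain = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
    return AudioSignal(samples=clean.samples + gain * segment, rate=clean.rate)


# ---------------------------------------------------------------------------
# Noise archetype generators
# ---------------------------------------------------------------------------

def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _slow_drift(n: int, rate: int, rng: np.random.Generator,
                cutoff_hz: float = 0.2, depth: float = 0.5) -> np.ndarray:
    """Smooth positive amplitude-drift envelope with mean ~1."""
    raw = rng.standard_normal(n)
    sos = butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
    drift = sosfilt(sos, raw)
    drift = drift / (np.std(drift) + 1e-12)
    return 1.0 + depth * np.tanh(drift)


def _harmonic_stream(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """One speech-like babble stream: harmonic tone with wandering f0,
    syllabic amplitude modulation, and random pauses."""
    t = np.arange(n) / rate
    f0 = rng.uniform(100.0, 250.0)
    # slow f0 wander, a few Hz
    f0_traj = f0 * (1.0 + 0.05 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t
                                        + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(f0_traj) / rate
    x = np.zeros(n)
    for h in range(1, 6):
        x += (1.0 / h) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    syllabic = 0.5 + 0.5 * np.sin(2 * np.pi * rng.uniform(3.0, 5.0) * t
                                  + rng.uniform(0, 2 * np.pi))
    gate = _slow_drift(n, rate, rng, cutoff_hz=0.5, depth=0.9)
    return x * syllabic * np.clip(gate, 0.0, None)


def make_noise(
    kind: str, duration: float, rate: int = 16_000, seed: int = 0
) -> AudioSignal:
    """Generate one of the four background-noise archetypes at unit RMS."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    if kind == "white":
        x = rng.standard_normal(n)
    elif kind == "street":
        # low-frequency rumble (<= 500 Hz emphasis) with slow level drift
        sos = butter(4, 500.0, btype="low", fs=rate, output="sos")
        x = sosfilt(sos, rng.standard_normal(n))
        x *= _slow_drift(n, rate, rng)
    elif kind == "sharp_speech":
        # sparse band-limited (300-3400 Hz) bursts with abrupt onsets
        sos = butter(4, (300.0, 3400.0), btype="band", fs=rate, output="sos")
        carrier = sosfilt(sos, rng.standard_normal(n))
        envelope = np.zeros(n)
        t0 = 0
        while t0 < n:
            burst = int(rng.uniform(0.05, 0.4) * rate)
            gap = int(rng.uniform(0.1, 0.8) * rate)
            envelope[t0:t0 + burst] = rng.uniform(0.5, 1.0)
            t0 += burst + gap
        x = carrier * envelope
    elif kind == "crowd":
        streams = [_harmonic_stream(n, rate, rng) for _ in range(8)]
        x = np.sum(streams, axis=0)
    else:
        raise ValueError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    return AudioSignal(samples=_unit_rms(x), rate=rate)


# ---------------------------------------------------------------------------
# logMMSE enhancement
# ---------------------------------------------------------------------------

def logmmse(noisy: AudioSignal, params: NRParams = NRParams()) -> AudioSignal:
    """Enhance a noisy signal with the log-spectral-amplitude MMSE estimator.

    Output has exactly the length of the input.  With ``gain_floor = 1`` the
    chain reduces to analysis + synthesis and reproduces the input up to
    overlap-add reconstruction error.
    """
    frame_len = int(round(params.fft_frame * noisy.rate))
    hop = max(int(round(frame_len * (1.0 - params.overlap))), 1)
    if len(noisy) < params.noise_init_frames * frame_len:
        raise ValueError(
            f"input too short for logMMSE: need at least "
            f"{params.noise_init_frames} frames of {frame_len} samples"
        )

    window = np.sqrt(np.hanning(frame_len + 1)[:frame_len])  # periodic sqrt-Hann
    pad = frame_len  # zero-pad both ends so every sample gets full window mass
    x = np.concatenate([np.zeros(pad), noisy.samples, np.zeros(pad)])
    n_frames = 1 + (len(x) - frame_len) // hop

    xi_min = 10.0 ** (params.xi_min_db / 10.0)
    noise_psd = None
    prev_gain2_gamma = None  # G^2 * gamma of the previous frame (A^2 / lambda_d)

    out = np.zeros(len(x))
    norm = np.zeros(len(x))
    for m in range(n_frames):
        seg = x[m * hop:m * hop + frame_len] * window
        spec = np.fft.rfft(seg)
        power = np.abs(spec) ** 2

        if noise_psd is None:
            noise_psd = power.copy() + 1e-12
        if m < params.noise_init_frames:
            noise_psd = 0.5 * noise_psd + 0.5 * (power + 1e-12)

        gamma = power / noise_psd
        if prev_gain2_gamma is None:
            xi = np.maximum(gamma - 1.0, 0.0)
        else:
            xi = (params.alpha_dd * prev_gain2_gamma
                  + (1.0 - params.alpha_dd) * np.maximum(gamma - 1.0, 0.0))
        xi = np.maximum(xi, xi_min)

        v = np.clip(xi * gamma / (1.0 + xi), 1e-50, 700.0)
        gain = (xi / (1.0 + xi)) * np.exp(0.5 * exp1(v))
        gain = np.clip(gain, params.gain_floor, 1.0)

        # speech-absence test on the mean log-likelihood ratio
        llr = float(np.mean(gamma * xi / (1.0 + xi) - np.log1p(xi)))
        if llr < params.vad_threshold:
            noise_psd = (params.noise_smooth * noise_psd
                         + (1.0 - params.noise_smooth) * power)

        prev_gain2_gamma = (gain ** 2) * gamma

        enhanced = np.fft.irfft(spec * gain, n=frame_len)
        out[m * hop:m * hop + frame_len] += enhanced * window
        norm[m * hop:m * hop + frame_len] += window ** 2

    out = out / np.maximum(norm, 1e-12)
    return AudioSignal(samples=out[pad:pad + len(noisy)], rate=noisy.rate)
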