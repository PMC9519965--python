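"""Spectral centre of gravity (COG) for consonant tokens.

COG is the power-weighted average frequency of a spectrum,
``sum(f * |S(f)|^p) / sum(|S(f)|^p)`` with the exponent ``p = 2``. The
spectrum is a single unwindowed transform of the whole annotated consonant
segment at the token's native sample rate (no sex-specific downsampling:
sibilant energy above 5.5 kHz must be retained). A Hann window and a
frame-averaged (Welch) spectrum are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .speech_io import SpeechToken

__all__ = [
    "MagnitudeSpectrum",
    "compute_spectrum",
    "center_of_gravity",
    "consonant_measure",
    "measure_consonant_tokens",
]

MIN_SEGMENT_SAMPLES = 32


@dataclass(frozen=True)
class MagnitudeSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing, DC included
    magnitudes: np.ndarray  # linear amplitude, >= 0

    def __post_init__(self) -> None:
        f, m = np.asarray(self.frequencies), np.asarray(self.magnitudes)
        if f.shape != m.shape:
            raise ValueError("frequency and magnitude arrays differ in length")
        if len(f) and (f[0] < 0 or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly increasing and >= 0")
        if np.any(m < 0):
            raise ValueError("magnitudes must be non-negative")


def compute_spectrum(
    segment: np.ndarray,
    sample_rate: float,
    window: str | None = None,
    averaged: bool = False,
) -> tuple[MagnitudeSpectrum | None, tuple[str, ...]]:
    """One-sided magnitude spectrum of a consonant segment.

    Returns (spectrum, flags); a segment shorter than 32 samples or all-zero
    is flagged missing rather than raised — missingness is data.
    """
    x = np.asarray(segment, dtype=np.float64)
    if len(x) < MIN_SEGMENT_SAMPLES:
        return None, ("segment_too_short",)
    if not np.any(x):
        return None, ("silent_segment",)
    if averaged:
        nper = min(len(x), 512)
        freqs, psd = welch(x, fs=sample_rate, nperseg=nper,
                           window=window or "hann")
        return MagnitudeSpectrum(freqs, np.sqrt(psd)), ()
    if window == "hann":
        x = x * np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    return MagnitudeSpectrum(freqs, spec), ()


def center_of_gravity(spectrum: MagnitudeSpectrum, p: float = 2.0) -> float:
    """Weighted mean frequency with weights |S(f)|^p (DC contributes at 0 Hz).

    Returns NaN for a spectrum with no positive weight.
    """
    w = np.asarray(spectrum.magnitudes, dtype=np.float64) ** p
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        return float("nan")
    return float((spectrum.frequencies * w).sum() / total)


def consonant_measure(
    token: SpeechToken, p: float = 2.0, window: str | None = None
) -> tuple[float, float, tuple[str, ...]]:
    """(COG in Hz, duration in s, flags) for one annotated consonant token."""
    seg, fs = token.segment()
    spectrum, flags = compute_spectrum(seg, fs, window=window)
    duration = token.annotation.duration
    if spectrum is None:
        return float("nan"), duration, flags
    cog = center_of_gravity(spectrum, p=p)
    if not np.isfinite(cog):
        flags = flags + ("zero_weight_spectrum",)
    return cog, duration, flags


def measure_consonant_tokens(tokens, p: float = 2.0) -> pd.DataFrame:
    """Measure every consonant token; one row per token with COG and duration."""
    rows = []
    for tok in tokens:
        if tok.is_vowel:
            continue
        cog, duration, flags = consonant_measure(tok, p=p)
        rows.append(
            {
                "token_id": tok.token_id,
                "participant": tok.participant,
                "group": tok.group,
                "sex": tok.sex,
                "session": tok.session,
                "word": tok.word,
                "phoneme": tok.phoneme,
                "repetition": tok.repetition,
                "cog_hz": cog,
                "duration_s": duration,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
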