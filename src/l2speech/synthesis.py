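"""Source-filter synthesis of vowel and consonant tokens with known truth.

Vowels are an impulse train at the fundamental passed through a cascade of
second-order resonators, one per formant, so the poles of the synthesis
filter are exactly the specified formant frequencies and bandwidths.
Consonants are white noise shaped in the frequency domain by a band filter
with a dB/octave tilt; the ground-truth spectral centre of gravity is the
closed-form power-weighted mean frequency of that filter response, so the
oracle carries no sampling noise.

Every function is deterministic given its seed/generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .design import VowelSpec, FricativeSpec

__all__ = [
    "VowelTruth",
    "FricativeTruth",
    "MALE_F1_DIVISOR",
    "MALE_F2_DIVISOR",
    "render_vowel",
    "synthesize_vowel",
    "analytic_band_cog",
    "synthesize_fricative",
]

# Male formant scale relative to the female-referenced specs; the inverse of
# the fixed normalization factors applied at the scoring stage.
MALE_F1_DIVISOR = 1.183
MALE_F2_DIVISOR = 1.172
MALE_F0_FACTOR = 120.0 / 210.0


@dataclass(frozen=True)
class VowelTruth:
    """Exact parameters a vowel token was rendered with."""

    phoneme: str
    sex: str
    f0: float
    formants: tuple[float, ...]
    bandwidths: tuple[float, ...]
    duration: float
    sample_rate: float

    @property
    def f1(self) -> float:
        return self.formants[0]

    @property
    def f2(self) -> float:
        return self.formants[1]


@dataclass(frozen=True)
class FricativeTruth:
    """Exact parameters of a band-noise consonant token."""

    phoneme: str
    band_low: float
    band_high: float
    spectral_tilt: float
    cog: float
    duration: float
    sample_rate: float


def _resonator_coeffs(freq: float, bw: float, fs: float):
    """Klatt-style digital resonator: poles at the given frequency/bandwidth."""
    t = 1.0 / fs
    c = -np.exp(-2.0 * np.pi * bw * t)
    b = 2.0 * np.exp(-np.pi * bw * t) * np.cos(2.0 * np.pi * freq * t)
    a = 1.0 - b - c
    return np.array([a]), np.array([1.0, -b, -c])


def render_vowel(
    f0: float,
    formants: tuple[float, ...],
    bandwidths: tuple[float, ...],
    duration: float,
    sample_rate: float,
) -> np.ndarray:
    """Render a stationary vowel; the filter poles ARE the formants.

    ``formants`` may instead contain per-sample trajectories (arrays of the
    token length) to render glides; resonator coefficients are then updated
    framewise (2.5 ms blocks).
    """
    if duration < 0.05:
        raise ValueError(f"vowel duration {duration:.4f} s < 0.05 s minimum")
    if len(formants) != len(bandwidths):
        raise ValueError("formants and bandwidths must have equal length")
    n = int(round(duration * sample_rate))
    track = [np.broadcast_to(np.asarray(f, float), (n,)) for f in formants]
    fmax = max(float(np.max(f)) for f in track)
    if fmax >= sample_rate / 2:
        raise ValueError(
            f"formant {fmax:.0f} Hz at or above Nyquist ({sample_rate / 2:.0f} Hz)"
        )

    # Impulse train at f0, shaped by a two-pole glottal lowpass (-12 dB/oct
    # above ~100 Hz) so the source has a realistic spectral slope; the
    # analysis-side pre-emphasis then restores roughly -6 dB/oct overall.
    source = np.zeros(n)
    period = sample_rate / f0
    source[np.round(np.arange(0.0, n - 0.5, period)).astype(int)] = 1.0
    g = np.exp(-2.0 * np.pi * 100.0 / sample_rate)
    for _ in range(2):
        source = lfilter([1.0 - g], [1.0, -g], source)

    stationary = all(float(np.ptp(f)) == 0.0 for f in track)
    if stationary:
        x = source
        for f, bw in zip(track, bandwidths):
            b, a = _resonator_coeffs(float(f[0]), bw, sample_rate)
            x = lfilter(b, a, x)
    else:
        block = max(1, int(round(0.0025 * sample_rate)))
        x = source.copy()
        for f, bw in zip(track, bandwidths):
            y = np.empty(n)
            zi = np.zeros(2)
            for start in range(0, n, block):
                stop = min(n, start + block)
                fc = float(f[(start + stop) // 2])
                b, a = _resonator_coeffs(fc, bw, sample_rate)
                y[start:stop], zi = lfilter(b, a, x[start:stop], zi=zi)
            x = y

    # 5 ms raised-cosine onset/offset ramps to avoid edge clicks.
    ramp = min(int(round(0.005 * sample_rate)), n // 2)
    if ramp > 0:
        env = np.ones(n)
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
        x = x * env
    peak = np.max(np.abs(x))
    return x / peak * 0.5 if peak > 0 else x


def synthesize_vowel(
    spec: VowelSpec,
    sex: str,
    sample_rate: float = 16000.0,
    seed=None,
    duration: float | None = None,
    speaker_offset: np.ndarray | None = None,
    f2_shift: float = 0.0,
) -> tuple[np.ndarray, VowelTruth]:
    """Sample token parameters from ``spec`` and render the waveform.

    ``speaker_offset`` is an optional vector of per-speaker multiplicative
    offsets (one per formant, around 1.0) representing a speaker's habitual
    deviation from the category mean; token-level scatter is drawn here.
    ``f2_shift`` (Hz, applied on the female scale) implements group/session
    production effects. The returned truth records the exact values used.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    means = np.array([spec.f1_mean, spec.f2_mean + f2_shift, spec.f3_mean, spec.f4_mean])
    if speaker_offset is None:
        speaker_offset = 1.0 + spec.between_sd_frac * rng.standard_normal(4)
    token_scatter = 1.0 + spec.within_sd_frac * rng.standard_normal(4)
    formants = means * np.asarray(speaker_offset) * token_scatter
    formants = np.maximum.accumulate(formants)  # keep the ordering sane

    f0 = spec.f0
    if sex == "male":
        divisors = np.array(
            [MALE_F1_DIVISOR, MALE_F2_DIVISOR, MALE_F2_DIVISOR, MALE_F2_DIVISOR]
        )
        formants = formants / divisors
        f0 = f0 * MALE_F0_FACTOR
    f0 = float(f0 * (1.0 + 0.03 * rng.standard_normal()))

    if duration is None:
        duration = float(
            np.clip(rng.normal(spec.duration_mean, spec.duration_sd), 0.08, 0.25)
        )
    duration = round(duration * sample_rate) / sample_rate  # snap to sample grid

    wave = render_vowel(f0, tuple(formants), spec.bandwidths, duration, sample_rate)
    truth = VowelTruth(
        phoneme=spec.phoneme,
        sex=sex,
        f0=f0,
        formants=tuple(float(f) for f in formants),
        bandwidths=tuple(spec.bandwidths),
        duration=duration,
        sample_rate=sample_rate,
    )
    return wave, truth


def _tilt_exponent(spectral_tilt: float) -> float:
    # amplitude |H(f)| = (f / band_low)^beta with tilt dB/octave:
    # 20*log10|H| = tilt * log2(f/fl)  =>  beta = tilt / (20*log10(2))
    return spectral_tilt / (20.0 * np.log10(2.0))


def analytic_band_cog(
    band_low: float, band_high: float, spectral_tilt: float = 0.0, p: float = 2.0
) -> float:
    """Closed-form centre of gravity of the tilted band filter's response.

    With |H(f)| = (f/fl)^beta on [fl, fh] and weight |H|^p, the COG is the
    ratio of two power-function integrals; a flat band (tilt 0, p any)
    reduces to the band midpoint.
    """
    beta = _tilt_exponent(spectral_tilt)
    e = p * beta  # weight exponent: f^e

    def power_integral(k: float) -> float:
        # integral of f^k over [fl, fh]
        if np.isclose(k, -1.0):
            return float(np.log(band_high / band_low))
        return float((band_high ** (k + 1) - band_low ** (k + 1)) / (k + 1))

    return power_integral(e + 1.0) / power_integral(e)


def synthesize_fricative(
    spec: FricativeSpec,
    sample_rate: float = 16000.0,
    seed=None,
    duration: float | None = None,
    band_scale: float = 1.0,
) -> tuple[np.ndarray, FricativeTruth]:
    """Render a band-noise consonant and its analytic ground-truth COG.

    ``band_scale`` multiplies both band edges (per-token jitter or a
    production effect); the truth COG scales with it exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if not 0 < spec.band_low < spec.band_high < sample_rate / 2:
        raise ValueError(
            f"band [{spec.band_low:.0f}, {spec.band_high:.0f}] Hz outside "
            f"(0, Nyquist={sample_rate / 2:.0f})"
        )
    scale = band_scale * float(
        np.exp(spec.band_jitter_frac * rng.standard_normal())
    )
    lo, hi = spec.band_low * scale, spec.band_high * scale
    # Per-token jitter may nudge the band past Nyquist; clip (the recorded
    # truth follows the clipped band, so the oracle stays exact).
    hi = min(hi, 0.99 * sample_rate / 2.0)
    if not 0 < lo < hi:
        raise ValueError(f"degenerate jittered band [{lo:.0f}, {hi:.0f}] Hz")
    if duration is None:
        duration = float(
            max(spec.duration_min, rng.normal(spec.duration_mean, spec.duration_sd))
        )
    if duration < 0.03:
        raise ValueError(f"consonant duration {duration:.4f} s < 0.03 s minimum")
    duration = round(duration * sample_rate) / sample_rate  # snap to sample grid

    # Random-phase spectral synthesis: the token's magnitude spectrum IS the
    # designed band response (no realization noise in the envelope), with
    # uniformly random phases. Token-to-token COG variability enters through
    # the band-edge jitter above, not through envelope sampling noise.
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    gain = np.zeros_like(freqs)
    in_band = (freqs >= lo) & (freqs <= hi)
    beta = _tilt_exponent(spec.spectral_tilt)
    gain[in_band] = (freqs[in_band] / lo) ** beta
    phase = np.exp(2j * np.pi * rng.random(len(freqs)))
    phase[0] = 1.0
    if n % 2 == 0:
        phase[-1] = 1.0  # Nyquist bin must stay real
    wave = np.fft.irfft(gain * phase, n)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak * 0.5

    truth = FricativeTruth(
        phoneme=spec.phoneme,
        band_low=lo,
        band_high=hi,
        spectral_tilt=spec.spectral_tilt,
        cog=analytic_band_cog(lo, hi, spec.spectral_tilt, p=2.0),
        duration=duration,
        sample_rate=sample_rate,
    )
    return wave, truth
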