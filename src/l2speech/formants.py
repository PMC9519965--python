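"""LPC-based vowel formant measurement.

The measurement chain reproduces the classic Praat-style procedure: vowels
are anti-alias filtered and downsampled to a sex-specific rate (8 kHz for
men, 11 kHz for women), pre-emphasized from 50 Hz, analysed framewise with
the Burg all-pole method at a sex-specific order (8 for men, 10 for women),
and the prediction-polynomial roots are converted to candidate formants.
Candidates are retained only if their frequency exceeds 90 Hz and their
bandwidth is below 400 Hz (both strict), with an additional cull within
50 Hz of the Nyquist frequency. Final F1/F2 are the means of the two lowest
retained candidates over the frames whose centres fall in the central 30 ms
of the annotated vowel.

An override table (token id -> LPC order) stands in for interactive visual
correction of tokens where the default order mis-tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .speech_io import SpeechToken
from .textgrids import AnnotationInterval

__all__ = [
    "LpcSettings",
    "FormantFrame",
    "FormantTrack",
    "FormantMeasure",
    "preprocess",
    "burg",
    "lpc_coefficients",
    "poles_to_formants",
    "track_formants",
    "vowel_measure",
    "measure_vowel_token",
    "measure_vowel_tokens",
    "apply_overrides",
]


@dataclass(frozen=True)
class LpcSettings:
    """Analysis settings for one sex-specific LPC path.

    Frame length/step, window shape and pre-emphasis reference follow the
    conventional defaults of Praat-style formant analysis; all are
    configurable.
    """

    target_rate: float
    order: int
    frame_length: float = 0.025
    frame_step: float = 0.00625
    preemphasis_hz: float = 50.0
    min_frequency: float = 90.0
    max_bandwidth: float = 400.0
    nyquist_margin: float = 50.0
    central_window: float = 0.030
    method: str = "burg"  # "burg" | "autocorrelation"

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("LPC order must be even and >= 2")
        if not 0 < self.frame_step <= self.frame_length:
            raise ValueError("need 0 < frame_step <= frame_length")
        if self.min_frequency >= self.target_rate / 2:
            raise ValueError("min_frequency must be below Nyquist")
        if self.method not in ("burg", "autocorrelation"):
            raise ValueError(f"unknown LPC method {self.method!r}")

    @classmethod
    def male(cls, **kw) -> "LpcSettings":
        return cls(target_rate=8000.0, order=8, **kw)

    @classmethod
    def female(cls, **kw) -> "LpcSettings":
        return cls(target_rate=11000.0, order=10, **kw)

    @classmethod
    def for_sex(cls, sex: str, **kw) -> "LpcSettings":
        if sex == "male":
            return cls.male(**kw)
        if sex == "female":
            return cls.female(**kw)
        raise ValueError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class FormantFrame:
    time: float  # frame centre, seconds on the original timeline
    candidates: tuple[tuple[float, float], ...]  # (frequency, bandwidth), ascending

    @property
    def degenerate(self) -> bool:
        return len(self.candidates) == 0


@dataclass(frozen=True)
class FormantTrack:
    token_id: str
    frames: tuple[FormantFrame, ...]
    settings: LpcSettings
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FormantMeasure:
    token_id: str
    f1: float  # NaN when flagged missing
    f2: float
    n_frames_used: int
    order_used: int
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.f1) or not np.isfinite(self.f2)


# ---------------------------------------------------------------------------
# signal conditioning

def preprocess(waveform: np.ndarray, sample_rate: float, settings: LpcSettings):
    """Downsample to the sex-specific analysis rate and pre-emphasize.

    Returns (conditioned waveform, analysis rate). Upsampling is refused:
    recordings below the analysis rate carry no information above their own
    Nyquist.
    """
    x = np.asarray(waveform, dtype=np.float64)
    fs = float(sample_rate)
    target = settings.target_rate
    if fs < target:
        raise ValueError(
            f"sample rate {fs:.0f} Hz below analysis rate {target:.0f} Hz; "
            "refusing to upsample"
        )
    if fs != target:
        frac = Fraction(int(round(target)), int(round(fs)))
        x = resample_poly(x, frac.numerator, frac.denominator)
        fs = target
    # First-difference pre-emphasis referenced at preemphasis_hz.
    a = np.exp(-2.0 * np.pi * settings.preemphasis_hz / fs)
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - a * x[:-1]
    return y, fs


# ---------------------------------------------------------------------------
# Burg all-pole estimation

def burg(frame: np.ndarray, order: int) -> np.ndarray:
    """Burg-method prediction coefficients [1, a1, ..., ap].

    Minimizes the summed forward and backward prediction error; the
    reflection-coefficient form guarantees |k| <= 1 and hence a
    minimum-phase (stable) polynomial A(z) = 1 + sum a_k z^-k.
    """
    x = np.asarray(frame, dtype=np.float64)
    n = len(x)
    if n <= order:
        raise ValueError(f"frame of {n} samples too short for order {order}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant frame: LPC undefined")

    f = x.copy()  # forward errors
    b = x.copy()  # backward errors
    a = np.zeros(order + 1)
    a[0] = 1.0
    for m in range(1, order + 1):
        fm = f[m:]
        bm = b[m - 1 : -1]
        den = fm @ fm + bm @ bm
        if den <= 0.0:
            break  # perfectly predicted; remaining coefficients stay zero
        k = -2.0 * (bm @ fm) / den
        a[1 : m + 1] = a[1 : m + 1] + k * a[m - 1 :: -1][: m]
        f_new = fm + k * bm
        b_new = bm + k * fm
        f[m:] = f_new
        b[m:] = b_new
    return a


def _autocorrelation_lpc(frame: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin on the biased autocorrelation (cross-check method)."""
    x = np.asarray(frame, dtype=np.float64)
    n = len(x)
    if n <= order:
        raise ValueError(f"frame of {n} samples too short for order {order}")
    r = np.array([x[: n - k] @ x[k:] for k in range(order + 1)]) / n
    if r[0] <= 0.0:
        raise ValueError("zero-energy frame: LPC undefined")
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for m in range(1, order + 1):
        acc = r[m] + a[1:m] @ r[1:m][::-1]
        k = -acc / err
        a[1 : m + 1] = a[1 : m + 1] + k * a[m - 1 :: -1][: m]
        err *= 1.0 - k * k
        if err <= 0.0:
            break
    return a


def lpc_coefficients(frame: np.ndarray, order: int, method: str = "burg") -> np.ndarray:
    if method == "burg":
        return burg(frame, order)
    return _autocorrelation_lpc(frame, order)


def poles_to_formants(
    coefficients: np.ndarray, sample_rate: float, settings: LpcSettings
) -> tuple[tuple[float, float], ...]:
    """Map prediction-polynomial roots to retained formant candidates.

    frequency = angle(r) * fs / (2*pi); bandwidth = -ln|r| * fs / pi.
    Retention: frequency > 90 Hz (strict), bandwidth < 400 Hz (strict),
    frequency below Nyquist minus the near-Nyquist margin. The empty tuple
    is a legal result.
    """
    roots = np.roots(coefficients)
    roots = roots[np.imag(roots) > 0.0]
    freqs = np.angle(roots) * sample_rate / (2.0 * np.pi)
    radii = np.abs(roots)
    bws = np.where(radii > 0, -np.log(np.maximum(radii, 1e-300)) * sample_rate / np.pi,
                   np.inf)
    keep = (
        (freqs > settings.min_frequency)
        & (bws < settings.max_bandwidth)
        & (freqs < sample_rate / 2.0 - settings.nyquist_margin)
    )
    cands = sorted(zip(freqs[keep], bws[keep]))
    return tuple((float(f), float(b)) for f, b in cands)


# ---------------------------------------------------------------------------
# framewise tracking and the central-window measure

def _gaussian_window(n: int) -> np.ndarray:
    # Gaussian-like analysis window (sigma = n/6), near-zero at the edges.
    t = np.arange(n) - (n - 1) / 2.0
    return np.exp(-0.5 * (6.0 * t / n) ** 2)


def track_formants(
    waveform: np.ndarray,
    sample_rate: float,
    interval: AnnotationInterval,
    settings: LpcSettings,
    token_id: str = "",
    order: int | None = None,
) -> FormantTrack:
    """Framewise formant candidates over the annotated vowel interval.

    Frames of ``frame_length`` seconds step through [start, end) at
    ``frame_step``; each frame is Gaussian-windowed and fitted with the
    configured LPC method. Near-silent or constant frames yield empty
    candidate lists; a vowel shorter than one frame yields an empty, flagged
    track.
    """
    if order is None:
        order = settings.order
    x, fs = preprocess(waveform, sample_rate, settings)
    i0 = int(np.floor(interval.start * fs + 1e-9))
    i1 = min(int(np.floor(interval.end * fs + 1e-9)), len(x))
    seg = x[i0:i1]
    flen = int(round(settings.frame_length * fs))
    step = int(round(settings.frame_step * fs))
    if len(seg) < flen or flen <= order:
        return FormantTrack(token_id, (), settings, flags=("too_short",))

    win = _gaussian_window(flen)
    # silence threshold relative to the segment's own peak
    floor = 1e-6 * max(np.max(np.abs(seg)), 1e-30)
    frames = []
    for start in range(0, len(seg) - flen + 1, step):
        chunk = seg[start : start + flen]
        t = interval.start + (start + flen / 2.0) / fs
        if np.max(np.abs(chunk)) <= floor or np.ptp(chunk) == 0.0:
            frames.append(FormantFrame(t, ()))
            continue
        try:
            a = lpc_coefficients(chunk * win, order, settings.method)
        except ValueError:
            frames.append(FormantFrame(t, ()))
            continue
        frames.append(FormantFrame(t, poles_to_formants(a, fs, settings)))

    flags = ()
    if all(fr.degenerate for fr in frames):
        flags = ("all_frames_degenerate",)
    return FormantTrack(token_id, tuple(frames), settings, flags=flags)


def vowel_measure(
    track: FormantTrack,
    interval: AnnotationInterval,
    order_used: int | None = None,
    mode: str = "mean",
) -> FormantMeasure:
    """F1/F2 from the central 30 ms of the vowel.

    Frames belong to the window if their centre lies within ``central_window``
    seconds centred on the interval midpoint; vowels shorter than the window
    use all frames. Frames with fewer than two retained candidates are
    excluded. ``mode="central"`` reads the single frame nearest the midpoint
    instead of averaging.
    """
    order_used = order_used if order_used is not None else track.settings.order
    mid = (interval.start + interval.end) / 2.0
    half = track.settings.central_window / 2.0
    usable = [
        fr for fr in track.frames
        if len(fr.candidates) >= 2 and abs(fr.time - mid) <= half + 1e-12
    ]
    if mode == "central" and usable:
        usable = [min(usable, key=lambda fr: abs(fr.time - mid))]
    if not usable:
        return FormantMeasure(
            track.token_id, np.nan, np.nan, 0, order_used,
            flags=track.flags + ("no_usable_frames",),
        )
    f1 = float(np.mean([fr.candidates[0][0] for fr in usable]))
    f2 = float(np.mean([fr.candidates[1][0] for fr in usable]))
    return FormantMeasure(track.token_id, f1, f2, len(usable), order_used, track.flags)


# ---------------------------------------------------------------------------
# token-level drivers

def measure_vowel_token(
    token: SpeechToken,
    settings: LpcSettings | None = None,
    order: int | None = None,
    mode: str = "mean",
) -> FormantMeasure:
    if settings is None:
        settings = LpcSettings.for_sex(token.sex)
    wave, fs = token.load()
    track = track_formants(
        wave, fs, token.annotation, settings, token_id=token.token_id, order=order
    )
    return vowel_measure(track, token.annotation,
                         order_used=order or settings.order, mode=mode)


def measure_vowel_tokens(
    tokens, settings_by_sex: dict[str, LpcSettings] | None = None
) -> pd.DataFrame:
    """Measure every vowel token; one row per token with F1, F2 and flags."""
    rows = []
    for tok in tokens:
        if not tok.is_vowel:
            continue
        settings = (settings_by_sex or {}).get(tok.sex) or LpcSettings.for_sex(tok.sex)
        m = measure_vowel_token(tok, settings)
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
                "f1_hz": m.f1,
                "f2_hz": m.f2,
                "duration_s": tok.annotation.duration,
                "n_frames_used": m.n_frames_used,
                "order_used": m.order_used,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)


def apply_overrides(
    measurements: pd.DataFrame, tokens, overrides: pd.DataFrame
) -> pd.DataFrame:
    """Re-analyse the tokens listed in an override table (token_id, lpc_order).

    Stands in for interactive inspection: listed tokens are re-measured at
    the per-token order, everything else is untouched, and the order used is
    recorded. Unknown token ids or invalid orders raise with the offenders
    listed.
    """
    if overrides.empty:
        return measurements.copy()
    bad_order = overrides[
        (overrides.lpc_order % 2 != 0)
        | (overrides.lpc_order < 4)
        | (overrides.lpc_order > 16)
    ]
    if len(bad_order):
        raise ValueError(
            "override orders must be even and within [4, 16]; offending rows: "
            + ", ".join(
                f"{r.token_id}={r.lpc_order}" for r in bad_order.itertuples()
            )
        )
    by_id = {t.token_id: t for t in tokens}
    unknown = [tid for tid in overrides.token_id if tid not in by_id]
    if unknown:
        raise KeyError(f"override table references unknown tokens: {unknown}")

    out = measurements.set_index("token_id", drop=False)
    for row in overrides.itertuples(index=False):
        tok = by_id[row.token_id]
        settings = LpcSettings.for_sex(tok.sex)
        m = measure_vowel_token(tok, settings, order=int(row.lpc_order))
        out.loc[row.token_id, ["f1_hz", "f2_hz", "n_frames_used", "order_used", "flags"]] = [
            m.f1, m.f2, m.n_frames_used, m.order_used, ";".join(m.flags),
        ]
    return out.reset_index(drop=True)
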