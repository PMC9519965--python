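"""Dataset I/O: WAV read/write, token table assembly from a study manifest.

A study dataset on disk is the layout written by
:func:`l2speech.study.generate_study`:

``participants.csv``, ``words.csv``, ``tokens.csv`` (the manifest),
``trials.csv``, ``judgments.csv``, ``config.json`` and, when audio was
rendered, ``audio/<token_id>.wav`` + ``audio/<token_id>.TextGrid`` with one
interval tier named ``"segments"`` whose target interval is labelled with
the token's phoneme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .textgrids import AnnotationInterval, read_textgrid, segment_duration

__all__ = [
    "SpeechToken",
    "TokenTableIssue",
    "read_wav",
    "write_wav",
    "build_token_table",
    "segment_duration",
]

SEGMENT_TIER = "segments"


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write mono PCM-16 WAV; float input in [-1, 1] is scaled."""
    x = np.asarray(waveform, dtype=np.float64)
    pcm = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(sample_rate), pcm)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV to float64 in [-1, 1] plus its sample rate."""
    fs, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return data, float(fs)


@dataclass
class SpeechToken:
    """One recorded (or synthesized) word token plus its annotation."""

    token_id: str
    participant: str
    group: str
    sex: str
    session: str
    word: str
    phoneme: str
    is_vowel: bool
    repetition: int
    block: int
    wav_path: Path | None
    sample_rate: float
    annotation: AnnotationInterval
    truth: dict = field(default_factory=dict)

    def load(self) -> tuple[np.ndarray, float]:
        if self.wav_path is None:
            raise FileNotFoundError(f"token {self.token_id} has no audio file")
        wave, fs = read_wav(self.wav_path)
        if self.annotation.end > len(wave) / fs + 1e-6:
            raise ValueError(
                f"token {self.token_id}: annotation [{self.annotation.start}, "
                f"{self.annotation.end}] extends past the waveform"
            )
        return wave, fs

    def segment(self) -> tuple[np.ndarray, float]:
        """Samples of the annotated target segment, half-open [start, end)."""
        wave, fs = self.load()
        # floor with an epsilon so grid-aligned times are not truncated by
        # floating-point fuzz
        i0 = int(np.floor(self.annotation.start * fs + 1e-9))
        i1 = int(np.floor(self.annotation.end * fs + 1e-9))
        return wave[i0:i1], fs


@dataclass(frozen=True)
class TokenTableIssue:
    token_id: str
    problem: str


_TRUTH_COLS = ("f1_true", "f2_true", "cog_true", "duration_true", "f0_true")


def build_token_table(
    root, require_audio: bool = True
) -> tuple[list[SpeechToken], list[TokenTableIssue]]:
    """Assemble SpeechTokens from a dataset root.

    Returns the token list and an itemized issue report; missing audio or
    annotation files are reported, never silently dropped. An empty or
    absent manifest yields an empty table plus one issue record.
    """
    root = Path(root)
    manifest_path = root / "tokens.csv"
    issues: list[TokenTableIssue] = []
    if not manifest_path.exists():
        return [], [TokenTableIssue("", f"no manifest at {manifest_path}")]
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        return [], [TokenTableIssue("", "empty manifest")]

    tokens: list[SpeechToken] = []
    for row in manifest.itertuples(index=False):
        token_id = row.token_id
        wav_path = root / row.wav_path if isinstance(row.wav_path, str) else None
        tg_path = root / row.textgrid_path if isinstance(row.textgrid_path, str) else None

        annotation = None
        if tg_path is not None and tg_path.exists():
            tiers = read_textgrid(tg_path)
            if SEGMENT_TIER not in tiers:
                issues.append(TokenTableIssue(token_id, f"no {SEGMENT_TIER!r} tier"))
                continue
            matches = [iv for iv in tiers[SEGMENT_TIER] if iv.label == row.phoneme]
            if not matches:
                issues.append(
                    TokenTableIssue(token_id, f"no interval labelled {row.phoneme!r}")
                )
                continue
            annotation = matches[0]  # several matches: take the first
        elif "seg_start" in manifest.columns and np.isfinite(row.seg_start):
            annotation = AnnotationInterval(row.phoneme, row.seg_start, row.seg_end)
        else:
            issues.append(TokenTableIssue(token_id, "missing annotation"))
            continue

        if wav_path is not None and not wav_path.exists():
            issues.append(TokenTableIssue(token_id, f"missing audio {wav_path.name}"))
            continue
        if wav_path is None and require_audio:
            issues.append(TokenTableIssue(token_id, "no audio rendered"))
            continue

        truth = {
            c: float(getattr(row, c))
            for c in _TRUTH_COLS
            if c in manifest.columns and np.isfinite(getattr(row, c))
        }
        tokens.append(
            SpeechToken(
                token_id=token_id,
                participant=row.participant,
                group=row.group,
                sex=row.sex,
                session=row.session,
                word=row.word,
                phoneme=row.phoneme,
                is_vowel=bool(row.is_vowel),
                repetition=int(row.repetition),
                block=int(row.block),
                wav_path=wav_path,
                sample_rate=float(row.sample_rate),
                annotation=annotation,
                truth=truth,
            )
        )
    return tokens, issues
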