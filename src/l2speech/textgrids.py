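"""Reading and writing Praat TextGrid annotation files (full text format).

Only the "full" (long) TextGrid dialect is supported; the abbreviated
"short" dialect is rejected with an explicit message, since a study's files
normally come from a single tool in a single dialect. Files are read as
UTF-8; UTF-16 with a byte-order mark is detected and decoded. Times are
seconds in double precision. Intervals are half-open [start, end) for
sample indexing (sample index = floor(t * fs)).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AnnotationInterval", "TextGridError", "read_textgrid", "write_textgrid",
           "segment_duration"]


class TextGridError(ValueError):
    """Malformed TextGrid; message names the offending line."""


@dataclass(frozen=True)
class AnnotationInterval:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: need 0 <= start < end"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_duration(interval: AnnotationInterval) -> float:
    """Duration in seconds of an annotated segment (end - start)."""
    return interval.duration


def _decode(raw: bytes) -> str:
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


_NUM = re.compile(r"=\s*([-+0-9.eE]+)\s*$")
_STR = re.compile(r'=\s*"(.*)"\s*$')


def read_textgrid(path) -> dict[str, list[AnnotationInterval]]:
    """Parse a full-format TextGrid into {tier name: [intervals]}.

    Empty-label intervals are preserved. Point (TextTier) tiers are not
    interval data and are skipped. Raises :class:`TextGridError` with a line
    number for malformed input.
    """
    path = Path(path)
    text = _decode(path.read_bytes())
    lines = text.splitlines()

    def fail(i: int, why: str):
        raise TextGridError(f"{path}, line {i + 1}: {why}")

    if not any('"TextGrid"' in ln for ln in lines[:4]):
        # Distinguish the short dialect (bare values, no 'item []') from junk.
        if any(ln.strip() == '"TextGrid"' for ln in lines[:4]):
            pass
        else:
            fail(0, "not a TextGrid file (missing TextGrid class header)")
    if not any("item" in ln for ln in lines):
        raise TextGridError(
            f"{path}: short-dialect TextGrid not supported; re-save in the "
            "full text format"
        )

    tiers: dict[str, list[AnnotationInterval]] = {}
    tier_name = None
    tier_kind = None
    start = end = None
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s.startswith("class"):
            m = _STR.search(s)
            if not m:
                fail(i, "unreadable tier class")
            tier_kind = m.group(1)
        elif s.startswith("name"):
            m = _STR.search(s)
            if not m:
                fail(i, "unreadable tier name")
            if tier_kind == "IntervalTier":
                tier_name = m.group(1)
                tiers[tier_name] = []
            else:
                tier_name = None
        elif s.startswith("xmin") and tier_name is not None:
            m = _NUM.search(s)
            if not m:
                fail(i, "unreadable xmin")
            start = float(m.group(1))
        elif s.startswith("xmax") and tier_name is not None:
            m = _NUM.search(s)
            if not m:
                fail(i, "unreadable xmax")
            end = float(m.group(1))
        elif s.startswith("text") and tier_name is not None:
            m = _STR.search(s)
            if m is None:
                fail(i, "unreadable interval text")
            if start is None or end is None:
                fail(i, "interval text before its xmin/xmax")
            if end < start:
                fail(i, f"interval end {end} precedes start {start}")
            if end > start:  # zero-width entries (tier headers re-matched) skipped
                tiers[tier_name].append(
                    AnnotationInterval(m.group(1).replace('""', '"'), start, end)
                )
            start = end = None

    for name, ivs in tiers.items():
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise TextGridError(
                    f"{path}: tier {name!r} has overlapping intervals "
                    f"[{a.start}, {a.end}] and [{b.start}, {b.end}]"
                )
    return tiers


def write_textgrid(path, tiers: dict[str, list[AnnotationInterval]],
                   xmin: float = 0.0, xmax: float | None = None) -> None:
    """Write tiers as a full-format UTF-8 TextGrid.

    Gaps between labelled intervals are filled with empty-label intervals so
    the file is valid for Praat.
    """
    if xmax is None:
        xmax = max((iv.end for ivs in tiers.values() for iv in ivs), default=1.0)
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t, (name, ivs) in enumerate(tiers.items(), start=1):
        ivs = sorted(ivs, key=lambda iv: iv.start)
        # fill gaps with empty labels
        filled: list[AnnotationInterval] = []
        cursor = xmin
        for iv in ivs:
            if iv.start > cursor + 1e-9:
                filled.append(AnnotationInterval("", cursor, iv.start))
            filled.append(iv)
            cursor = iv.end
        if xmax > cursor + 1e-9:
            filled.append(AnnotationInterval("", cursor, xmax))
        out += [
            f"    item [{t}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin:.6f}",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(filled)}",
        ]
        for k, iv in enumerate(filled, start=1):
            label = iv.label.replace('"', '""')
            out += [
                f"        intervals [{k}]:",
                f"            xmin = {iv.start:.6f}",
                f"            xmax = {iv.end:.6f}",
                f'            text = "{label}"',
            ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
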