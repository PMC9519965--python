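"""Diagnostic plots (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .formants import FormantTrack


def plot_formant_track(
    waveform: np.ndarray,
    sample_rate: float,
    track: FormantTrack,
    ax=None,
):
    """Wide-band spectrogram with the retained formant candidates overlaid.

    The classic visual check: candidate tracks should ride the dark formant
    bands. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    nfft = max(64, int(0.005 * sample_rate))  # ~5 ms analysis -> wide-band
    ax.specgram(waveform, NFFT=nfft, Fs=sample_rate, noverlap=nfft // 2,
                cmap="Greys")
    for fr in track.frames:
        for f, _bw in fr.candidates[:2]:
            ax.plot(fr.time, f, "r.", markersize=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(track.token_id or "formant track")
    return ax
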