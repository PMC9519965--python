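"""Simulated AXB discrimination responses and musical-task score tables.

Each participant completes, per session, ``2 x tokens_per_phoneme`` AXB
trials per contrast (each word of a minimal pair serves once as the middle
item). Correctness is a Bernoulli draw at the cell probability from the
effect model; reaction times are truncated-normal in milliseconds and go
missing at the lapse (timeout) rate, in which case the trial is flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import BehavioralEffectModel, StudyDesign

__all__ = ["generate_behavioral"]

MUSIC_SUBTESTS = ("timbre", "duration", "tonal_memory")


def generate_behavioral(
    design: StudyDesign,
    model: BehavioralEffectModel | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (AXB trial table, musical-task score table).

    The trial table has one row per trial: participant, group, session,
    contrast, trial, correct (0/1), rt_ms (NaN on lapse), lapse flag.
    """
    model = model or BehavioralEffectModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_trials = 2 * design.tokens_per_phoneme

    a = (model.rt_min - model.rt_mean) / model.rt_sd
    b = (model.rt_max - model.rt_mean) / model.rt_sd

    # One row per (participant, session, contrast, trial), fully vectorized.
    participants = design.participants
    groups = [design.group_of(p) for p in participants]
    contrasts = design.contrast_names
    cells = [
        (p, g, s, c)
        for p, g in zip(participants, groups)
        for s in design.sessions
        for c in contrasts
    ]
    n_cells = len(cells)
    p_correct = np.repeat(
        [model.p_correct(c, g, s) for (_, g, s, c) in cells], n_trials
    )
    n_rows = n_cells * n_trials
    correct = rng.random(n_rows) < p_correct
    lapse = rng.random(n_rows) < model.lapse_rate
    rts = stats.truncnorm.rvs(
        a, b, loc=model.rt_mean, scale=model.rt_sd,
        size=n_rows, random_state=rng,
    )
    rts[lapse] = np.nan
    trials = pd.DataFrame(
        {
            "participant": np.repeat([c[0] for c in cells], n_trials),
            "group": np.repeat([c[1] for c in cells], n_trials),
            "session": np.repeat([c[2] for c in cells], n_trials),
            "contrast": np.repeat([c[3] for c in cells], n_trials),
            "trial": np.tile(np.arange(1, n_trials + 1), n_cells),
            "correct": correct.astype(int),
            "rt_ms": rts,
            "lapse": lapse,
        }
    )

    music_recs = []
    for participant in design.participants:
        group = design.group_of(participant)
        ability = rng.normal(0.75, 0.08)
        for session in design.sessions:
            for subtest in MUSIC_SUBTESTS:
                acc = float(np.clip(ability + rng.normal(0, 0.05), 0, 1))
                music_recs.append(
                    (participant, group, session, subtest,
                     round(acc * 100, 1), float(rng.normal(1100, 200)))
                )
    music = pd.DataFrame(
        music_recs,
        columns=["participant", "group", "session", "subtest",
                 "accuracy_pct", "rt_ms"],
    )
    return trials, music
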