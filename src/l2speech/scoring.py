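"""From raw measurements and trials to the analysis variables.

Steps, in the order the analysis applies them:

1. perceptual exclusion — a consonant token is kept only if at least two
   judges labelled it as the experimental target;
2. sex normalization — male F1 is multiplied by 1.183 and male F2 by 1.172
   (the study's corpus-derived female/male mean ratios), after which all
   participants are analysed as a single group;
3. aggregation — token-level measurements and trial-level responses are
   reduced to participant x session x variable means (accuracy as percent
   correct of attempted trials, RT over correct non-missing trials);
4. difference/distance scoring — per participant and variable,
   ``difference = post - pre`` and ``distance = |difference|``.

The difference sign convention (positive = increase from pre to post) is a
single configuration point; the reversed convention is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFactors",
    "FIXED_FACTORS",
    "estimate_normalization",
    "normalize_male_formants",
    "exclude_misjudged",
    "aggregate_behavioral",
    "aggregate_acoustic",
    "build_scores",
]


@dataclass(frozen=True)
class NormalizationFactors:
    f1_ratio: float
    f2_ratio: float
    provenance: str  # "fixed" | "estimated"

    def __post_init__(self) -> None:
        if self.f1_ratio <= 0 or self.f2_ratio <= 0:
            raise ValueError("normalization ratios must be positive")


#: The study's corpus-derived constants: female mean / male mean per formant.
FIXED_FACTORS = NormalizationFactors(f1_ratio=1.183, f2_ratio=1.172, provenance="fixed")


def estimate_normalization(rows: pd.DataFrame) -> NormalizationFactors:
    """Female-to-male mean ratio of F1 and F2 over all vowel rows."""
    sexes = set(rows["sex"].unique())
    if not {"male", "female"} <= sexes:
        raise ValueError(
            "both sexes required to estimate normalization factors; "
            "use FIXED_FACTORS for a single-sex dataset"
        )
    means = rows.groupby("sex")[["f1_hz", "f2_hz"]].mean()
    return NormalizationFactors(
        f1_ratio=float(means.loc["female", "f1_hz"] / means.loc["male", "f1_hz"]),
        f2_ratio=float(means.loc["female", "f2_hz"] / means.loc["male", "f2_hz"]),
        provenance="estimated",
    )


def normalize_male_formants(
    rows: pd.DataFrame, factors: NormalizationFactors = FIXED_FACTORS
) -> pd.DataFrame:
    """Scale male F1/F2 by the factors; female rows pass through unchanged.

    A ``formants_normalized`` provenance column guards against accidental
    double application.
    """
    if "formants_normalized" in rows.columns and rows["formants_normalized"].any():
        raise ValueError("rows already normalized (formants_normalized is set)")
    out = rows.copy()
    male = out["sex"] == "male"
    out.loc[male, "f1_hz"] = out.loc[male, "f1_hz"] * factors.f1_ratio
    out.loc[male, "f2_hz"] = out.loc[male, "f2_hz"] * factors.f2_ratio
    out["formants_normalized"] = True
    out.attrs["normalization"] = factors
    return out


def exclude_misjudged(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep a consonant row iff >= 2 judge labels equal the target phoneme.

    ``rows`` carries ``target``, ``judge1``, ``judge2`` and optionally
    ``judge3`` (null where no third judge was consulted). Rows whose first
    two judgments are missing are flagged and excluded, never silently kept.
    The report gives counts and the discard percentage at one decimal.
    """
    j3 = rows["judge3"] if "judge3" in rows.columns else pd.Series(
        [None] * len(rows), index=rows.index
    )
    missing = rows["judge1"].isna() | rows["judge2"].isna()
    votes = (
        (rows["judge1"] == rows["target"]).astype(int)
        + (rows["judge2"] == rows["target"]).astype(int)
        + (j3 == rows["target"]).astype(int)
    )
    keep = (votes >= 2) & ~missing
    kept = rows[keep]
    n, n_kept = len(rows), int(keep.sum())
    n_discarded = n - n_kept
    n_missing = int(missing.sum())
    pct = 100.0 * n_discarded / n if n else 0.0
    report = {
        "n_input": n,
        "n_kept": n_kept,
        "n_discarded": n_discarded,
        "n_missing_judgments": n_missing,
        "discarded_pct": round(pct, 1),
        "discarded_pct_str": f"{pct:.1f}%",
    }
    logger.info(
        "judge exclusion: %d of %d consonant rows discarded (%s)",
        n_discarded, n, report["discarded_pct_str"],
    )
    return kept, report


def aggregate_behavioral(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant x session x contrast accuracy (%) and mean RT (ms).

    Accuracy counts every attempted trial; RT averages correct trials with a
    recorded (non-missing) response only. Cells with zero attempted trials
    are absent and logged.
    """
    keys = ["participant", "group", "session", "contrast"]
    t = trials.copy()
    t["rt_valid"] = t["rt_ms"].where((t["correct"] == 1) & t["rt_ms"].notna())
    agg = (
        t.groupby(keys, sort=True)
        .agg(
            accuracy_pct=("correct", lambda c: 100.0 * c.mean()),
            mean_rt_ms=("rt_valid", "mean"),
            n_trials=("correct", "size"),
            n_rt=("rt_valid", "count"),
        )
        .reset_index()
    )
    empty_rt = agg["n_rt"] == 0
    if empty_rt.any():
        logger.info("%d cells have no usable RT trials", int(empty_rt.sum()))
    return agg


def aggregate_acoustic(
    measurements: pd.DataFrame, value_cols: dict[str, str]
) -> pd.DataFrame:
    """Token-level -> participant-level means per phoneme and session.

    ``value_cols`` maps measurement columns to variable prefixes, e.g.
    ``{"f2_hz": "F2", "duration_s": "dur"}``; output is long format with a
    ``variable`` column like ``"F2:/iy/"``. Flagged-missing values are
    excluded from the mean (listwise within the cell).
    """
    frames = []
    for col, prefix in value_cols.items():
        sub = measurements[np.isfinite(measurements[col])]
        agg = (
            sub.groupby(["participant", "group", "session", "phoneme"])[col]
            .mean()
            .reset_index()
        )
        agg["variable"] = prefix + ":/" + agg["phoneme"] + "/"
        agg = agg.rename(columns={col: "value"}).drop(columns="phoneme")
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def build_scores(
    values: pd.DataFrame,
    sign: str = "post-minus-pre",
    pre_label: str = "pre",
    post_label: str = "post",
) -> pd.DataFrame:
    """Difference and distance scores per participant and variable.

    ``values`` is long format with columns participant, group, session,
    variable, value. Participants missing either session for a variable are
    excluded from that variable with a log record.
    """
    if sign not in ("post-minus-pre", "pre-minus-post"):
        raise ValueError(f"unknown sign convention {sign!r}")
    wide = values.pivot_table(
        index=["participant", "group", "variable"],
        columns="session",
        values="value",
        aggfunc="mean",
    ).reset_index()
    if pre_label not in wide.columns or post_label not in wide.columns:
        raise ValueError("values table must contain both sessions")
    incomplete = wide[pre_label].isna() | wide[post_label].isna()
    if incomplete.any():
        for r in wide[incomplete].itertuples():
            logger.info(
                "participant %s missing a session for %s; excluded",
                r.participant, r.variable,
            )
        wide = wide[~incomplete]
    diff = wide[post_label] - wide[pre_label]
    if sign == "pre-minus-post":
        diff = -diff
    out = pd.DataFrame(
        {
            "participant": wide["participant"],
            "group": wide["group"],
            "variable": wide["variable"],
            "pre": wide[pre_label],
            "post": wide[post_label],
            "difference": diff,
            "distance": diff.abs(),
        }
    )
    out.attrs["sign"] = sign
    return out.reset_index(drop=True)
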