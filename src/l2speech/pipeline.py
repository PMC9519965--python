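"""Staged pipeline: generate -> measure -> score -> analyze -> report.

Stages communicate through documented CSV/JSON artifacts under a dataset
root, so every intermediate is inspectable and any stage can be re-run on
the previous stage's outputs:

``measure``  reads ``tokens.csv`` + audio, writes
             ``measurements_vowels.csv``, ``measurements_consonants.csv``
             and ``measure_issues.json``;
``score``    applies judge exclusion, sex normalization and aggregation,
             writes ``scores.csv``, ``exclusion_report.json``;
``analyze``  runs the MANOVA families, writes ``statistics.json``;
``report``   renders ``report.txt``.

Every stage is a pure function of its input artifacts plus the resolved
configuration, which is written beside the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring, stats
from .design import (
    BehavioralEffectModel,
    ProductionEffectModel,
    StudyDesign,
)
from .formants import apply_overrides, measure_vowel_tokens
from .spectral import measure_consonant_tokens
from .speech_io import build_token_table
from .study import StudyDataset, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "stage_generate", "stage_measure", "stage_score",
           "stage_analyze", "stage_report", "ANALYSIS_FAMILIES"]


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the offending items."""


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    out_dir: str = "study"
    seed: int = 0
    sample_rate: float = 16000.0
    audio: bool = True
    null_effects: bool = False  # zero group-by-session effects everywhere
    judge_error_rate: float = 0.048
    normalization: str = "fixed"  # "fixed" | "estimated"
    sign: str = "post-minus-pre"
    design: dict = field(default_factory=dict)
    families: list = field(default_factory=list)  # empty = all

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.normalization not in ("fixed", "estimated"):
            raise PipelineError(f"config: bad normalization {cfg.normalization!r}")
        if cfg.sign not in ("post-minus-pre", "pre-minus-post"):
            raise PipelineError(f"config: bad sign convention {cfg.sign!r}")
        return cfg

    def study_design(self) -> StudyDesign:
        return StudyDesign(**self.design) if self.design else StudyDesign()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def stage_generate(config: PipelineConfig) -> StudyDataset:
    design = config.study_design()
    behavioral = (
        BehavioralEffectModel.null() if config.null_effects else BehavioralEffectModel()
    )
    production = (
        ProductionEffectModel.null() if config.null_effects else ProductionEffectModel()
    )
    dataset = generate_study(
        design=design,
        behavioral_model=behavioral,
        production_model=production,
        seed=config.seed,
        out_dir=config.out_dir,
        sample_rate=config.sample_rate,
        audio=config.audio,
        judge_error_rate=config.judge_error_rate,
    )
    _write_json(Path(config.out_dir) / "pipeline_config.json", asdict(config))
    logger.info(
        "generate: %d vowel + %d consonant tokens under %s",
        dataset.n_vowel_tokens, dataset.n_consonant_tokens, dataset.root,
    )
    return dataset


def stage_measure(root, overrides: pd.DataFrame | None = None) -> None:
    root = Path(root)
    tokens, issues = build_token_table(root)
    if not tokens:
        raise PipelineError(
            f"measure: no usable tokens under {root} "
            f"({len(issues)} issues; first: {issues[0].problem if issues else 'none'})"
        )
    vowels = measure_vowel_tokens(tokens)
    if overrides is not None and len(overrides):
        vowels = apply_overrides(vowels, tokens, overrides)
    consonants = measure_consonant_tokens(tokens)
    vowels.to_csv(root / "measurements_vowels.csv", index=False)
    consonants.to_csv(root / "measurements_consonants.csv", index=False)
    _write_json(
        root / "measure_issues.json",
        [{"token_id": i.token_id, "problem": i.problem} for i in issues],
    )
    logger.info(
        "measure: %d vowel rows, %d consonant rows, %d issues",
        len(vowels), len(consonants), len(issues),
    )


def stage_score(root, normalization: str = "fixed",
                sign: str = "post-minus-pre") -> None:
    root = Path(root)
    required = ["measurements_vowels.csv", "measurements_consonants.csv",
                "judgments.csv", "trials.csv"]
    missing = [f for f in required if not (root / f).exists()]
    if missing:
        raise PipelineError(f"score: missing upstream artifacts {missing}")
    vowels = pd.read_csv(root / "measurements_vowels.csv")
    consonants = pd.read_csv(root / "measurements_consonants.csv")
    judgments = pd.read_csv(root / "judgments.csv")
    trials = pd.read_csv(root / "trials.csv")

    judged = consonants.merge(
        judgments.rename(columns={"target": "judged_target"}),
        on="token_id", how="left",
    )
    judged["target"] = judged["phoneme"]
    kept, report = scoring.exclude_misjudged(judged)
    _write_json(root / "exclusion_report.json", report)

    factors = (
        scoring.estimate_normalization(vowels)
        if normalization == "estimated" else scoring.FIXED_FACTORS
    )
    vowels = scoring.normalize_male_formants(vowels, factors)

    acoustic = pd.concat(
        [
            scoring.aggregate_acoustic(
                vowels, {"f1_hz": "F1", "f2_hz": "F2", "duration_s": "vdur"}
            ),
            scoring.aggregate_acoustic(
                kept, {"cog_hz": "COG", "duration_s": "cdur"}
            ),
        ],
        ignore_index=True,
    )
    behavioral = scoring.aggregate_behavioral(trials)
    behavioral_long = pd.concat(
        [
            behavioral.assign(
                variable="acc:" + behavioral["contrast"],
                value=behavioral["accuracy_pct"],
            )[["participant", "group", "session", "variable", "value"]],
            behavioral.assign(
                variable="rt:" + behavioral["contrast"],
                value=behavioral["mean_rt_ms"],
            )[["participant", "group", "session", "variable", "value"]],
        ],
        ignore_index=True,
    )
    values = pd.concat([acoustic, behavioral_long], ignore_index=True)
    scores = scoring.build_scores(values, sign=sign)
    scores.to_csv(root / "scores.csv", index=False)
    _write_json(
        root / "score_meta.json",
        {"normalization": asdict(factors), "sign": sign, "n_scores": len(scores)},
    )
    logger.info("score: %d participant-variable scores", len(scores))


#: family name -> (variable prefix, phoneme/contrast labels, value column)
def _families(scores: pd.DataFrame) -> dict[str, tuple[list, str]]:
    have = set(scores["variable"])

    def pick(prefix, labels, wrap):
        return [v for v in (f"{prefix}:{wrap(l)}" for l in labels) if v in have]

    vowel_contrasts = ["iy-ih", "eh-ae", "ah-aa"]
    consonant_contrasts = ["z-dh", "d-dh", "s-th", "t-th"]
    vowels = ["iy", "ih", "eh", "ae", "ah", "aa"]
    consonants = ["z", "dh", "d", "th", "s", "t"]
    slash = lambda l: f"/{l}/"
    plain = lambda l: l
    fams = {
        "vowel_accuracy_difference": (pick("acc", vowel_contrasts, plain), "difference"),
        "consonant_accuracy_difference": (
            pick("acc", consonant_contrasts, plain), "difference"),
        "vowel_rt_difference": (pick("rt", vowel_contrasts, plain), "difference"),
        "consonant_rt_difference": (
            pick("rt", consonant_contrasts, plain), "difference"),
        "f1_difference": (pick("F1", vowels, slash), "difference"),
        "f2_difference": (pick("F2", vowels, slash), "difference"),
        "f1_distance": (pick("F1", vowels, slash), "distance"),
        "f2_distance": (pick("F2", vowels, slash), "distance"),
        "vowel_duration_distance": (pick("vdur", vowels, slash), "distance"),
        "cog_difference": (pick("COG", consonants, slash), "difference"),
        "cog_distance": (pick("COG", consonants, slash), "distance"),
        "consonant_duration_distance": (pick("cdur", consonants, slash), "distance"),
    }
    return {k: v for k, v in fams.items() if len(v[0]) >= 2}


ANALYSIS_FAMILIES = [
    "vowel_accuracy_difference", "consonant_accuracy_difference",
    "vowel_rt_difference", "consonant_rt_difference",
    "f1_difference", "f2_difference", "f1_distance", "f2_distance",
    "vowel_duration_distance", "cog_difference", "cog_distance",
    "consonant_duration_distance",
]


def stage_analyze(root, families=None, blinding_table=None) -> dict:
    root = Path(root)
    scores_path = root / "scores.csv"
    if not scores_path.exists():
        raise PipelineError(f"analyze: missing upstream artifact {scores_path}")
    scores = pd.read_csv(scores_path)
    available = _families(scores)
    wanted = families or list(available)
    results: dict = {"families": {}}
    for fam in wanted:
        if fam not in available:
            raise PipelineError(f"analyze: unknown or unpopulated family {fam!r}")
        variables, value_col = available[fam]
        try:
            results["families"][fam] = stats.manova_family(
                scores, variables, value_col=value_col
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            results["families"][fam] = {"error": str(err)}
    results["baseline_diagnostics"] = stats.baseline_diagnostics(scores).to_dict(
        orient="records"
    )
    if blinding_table is not None:
        res = stats.chi_square_independence(blinding_table)
        results["blinding"] = {
            "table": np.asarray(blinding_table).tolist(),
            "chi2": res.statistic,
            "df": res.df[0],
            "p": res.pvalue,
        }
    _write_json(root / "statistics.json", results)
    logger.info("analyze: %d families", len(results["families"]))
    return results


def stage_report(root) -> str:
    root = Path(root)
    stats_path = root / "statistics.json"
    if not stats_path.exists():
        raise PipelineError(f"report: missing upstream artifact {stats_path}")
    results = json.loads(stats_path.read_text())
    lines = ["L2 speech pipeline report", "=" * 60]
    excl_path = root / "exclusion_report.json"
    if excl_path.exists():
        excl = json.loads(excl_path.read_text())
        lines.append(
            f"Judge exclusion: {excl['n_discarded']} of {excl['n_input']} "
            f"consonant tokens discarded ({excl['discarded_pct_str']})"
        )
    for fam, res in results["families"].items():
        lines += ["", f"[{fam}]"]
        if "error" in res:
            lines.append(f"  not testable: {res['error']}")
            continue
        lines.append(res["summary"])
        if not res["prescreen"]["passed"]:
            lines.append(
                "  note: inter-correlation prescreen failed "
                f"(min |r| = {res['prescreen']['min_abs_r']:.2f})"
            )
    if "blinding" in results:
        b = results["blinding"]
        lines += [
            "",
            "Blinding check (group x correct guess): "
            f"chi2({b['df']}) = {b['chi2']:.2f}, p = {b['p']:.2f}",
        ]
    text = "\n".join(lines) + "\n"
    (root / "report.txt").write_text(text)
    return text


def run_pipeline(config: PipelineConfig, blinding_table=None) -> dict:
    """Run every stage in order; returns the analysis results dict."""
    stage_generate(config)
    stage_measure(config.out_dir)
    stage_score(config.out_dir, config.normalization, config.sign)
    results = stage_analyze(config.out_dir, config.families or None, blinding_table)
    stage_report(config.out_dir)
    return results
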