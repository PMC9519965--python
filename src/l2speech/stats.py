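"""Two-group multivariate inference on difference/distance scores.

The central object is :class:`TwoGroupManova`, a statsmodels-style model:
build it from a score matrix (participants x dependent variables) and a
two-level group factor, call :meth:`~TwoGroupManova.fit`, and read the
:class:`ManovaResults` — Wilks' lambda with its exact two-group F
transform, univariate follow-up ANOVAs, and a ``summary()`` table.

For a one-way design with two groups and ``p`` dependent variables, with
``H`` the between-group and ``E`` the within-group cross-product matrices,

    lambda = det(E) / det(E + H)
    F = ((N - p - 1) / p) * (1 - lambda) / lambda   on (p, N - p - 1) df

which is exact (not an approximation) when the number of groups is two.
Supporting tests used around the MANOVA: one-way univariate ANOVA (equal to
the squared pooled-variance t), one-sample one-tailed t-tests of mean
change against zero, a Pearson chi-square test of independence without
continuity correction (group-guess blinding check), an inter-correlation
prescreen (all pairwise |r| > 0.30, advisory), and baseline diagnostics
(point-biserial group-baseline correlation, pre/post reliability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoGroupManova",
    "ManovaResults",
    "TestResult",
    "intercorrelation_check",
    "anova_univariate",
    "one_sample_t",
    "chi_square_independence",
    "baseline_diagnostics",
    "manova_family",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    pvalue: float
    tail: str = "two"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


# ---------------------------------------------------------------------------
# univariate helpers

def anova_univariate(values, groups) -> TestResult:
    """One-way F test for two groups on (1, N-2) df; equals t**2."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {len(levels)}")
    a, b = values[groups == levels[0]], values[groups == levels[1]]
    n = len(values)
    grand = values.mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss_within <= 0.0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ss_between / 1.0) / (ss_within / (n - 2))
    p = float(sps.f.sf(f, 1, n - 2))
    return TestResult(float(f), (1, n - 2), p, tail="two", name="one-way ANOVA")


def one_sample_t(scores, mu: float = 0.0, tail: str = "one") -> TestResult:
    """t = (mean - mu) / (sd / sqrt(n)) on n-1 df.

    ``tail="one"`` tests the directional alternative mean > mu (improvement
    positive under the post-minus-pre sign convention).
    """
    x = np.asarray(scores, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        if x.mean() == mu:
            # degenerate but well-defined: no evidence either way
            p = 0.5 if tail == "one" else 1.0
            return TestResult(0.0, (n - 1,), p, tail=tail, name="one-sample t")
        raise ValueError("zero variance with nonzero effect: t undefined")
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    if tail == "one":
        p = float(sps.t.sf(t, n - 1))
    elif tail == "two":
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(float(t), (n - 1,), p, tail=tail, name="one-sample t")


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    obs = np.asarray(table, dtype=np.float64)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total: expected counts undefined")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if np.any(expected <= 0):
        raise ValueError("non-positive expected count")
    return TestResult(float(chi2), (int(dof),), float(p), tail="two",
                      name="chi-square independence")


def intercorrelation_check(
    scores, threshold: float = 0.30
) -> tuple[bool, np.ndarray, list[str]]:
    """Pairwise Pearson correlations among dependent variables.

    Passes iff every off-diagonal |r| exceeds the threshold. Advisory: the
    caller is expected to warn, not abort, on failure. Constant columns make
    the correlation undefined and fail with a diagnostic.
    """
    x = np.asarray(scores, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 rows and >= 2 variables")
    notes = []
    constant = np.isclose(x.std(axis=0), 0.0)
    if constant.any():
        for j in np.flatnonzero(constant):
            notes.append(f"variable {j} is constant; correlation undefined")
        r = np.full((x.shape[1], x.shape[1]), np.nan)
        np.fill_diagonal(r, 1.0)
        return False, r, notes
    r = np.corrcoef(x, rowvar=False)
    off = np.abs(r[~np.eye(len(r), dtype=bool)])
    passed = bool(np.all(off > threshold))
    if not passed:
        notes.append(
            f"minimum off-diagonal |r| = {off.min():.3f} <= {threshold:.2f}"
        )
    return passed, r, notes


# ---------------------------------------------------------------------------
# the MANOVA model

def _cross_products(x: np.ndarray, groups: np.ndarray):
    """Between-group (H) and within-group (E) cross-product matrices."""
    grand = x.mean(axis=0)
    p = x.shape[1]
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for g in pd.unique(groups):
        xg = x[groups == g]
        d = xg.mean(axis=0) - grand
        h += len(xg) * np.outer(d, d)
        r = xg - xg.mean(axis=0)
        e += r.T @ r
    return h, e


class TwoGroupManova:
    """One-way MANOVA with a two-level between-subject factor.

    Parameters
    ----------
    endog : (n, p) array or DataFrame
        Score matrix, one row per participant, one column per dependent
        variable. Rows with any missing value are dropped listwise.
    groups : length-n sequence
        Two-level group labels aligned with the rows of ``endog``.
    """

    def __init__(self, endog, groups):
        if isinstance(endog, pd.DataFrame):
            self.var_names = list(endog.columns)
            x = endog.to_numpy(dtype=np.float64)
        else:
            x = np.asarray(endog, dtype=np.float64)
            if x.ndim == 1:
                x = x[:, None]
            self.var_names = [f"y{j + 1}" for j in range(x.shape[1])]
        groups = np.asarray(groups)
        if len(groups) != len(x):
            raise ValueError("endog and groups differ in length")
        ok = np.all(np.isfinite(x), axis=1)
        self.n_dropped = int((~ok).sum())
        self.endog = x[ok]
        self.groups = groups[ok]
        self.levels = pd.unique(self.groups)
        if len(self.levels) != 2:
            raise ValueError(f"expected exactly two groups, got {list(self.levels)}")
        n, p = self.endog.shape
        for lvl in self.levels:
            if (self.groups == lvl).sum() <= p:
                raise ValueError(
                    f"group {lvl!r} needs more members than dependent variables ({p})"
                )

    @classmethod
    def from_scores(cls, score_table: pd.DataFrame, variables,
                    value_col: str = "difference") -> "TwoGroupManova":
        """Build from a long-format score table (see scoring.build_scores)."""
        sub = score_table[score_table["variable"].isin(variables)]
        wide = sub.pivot_table(index=["participant", "group"],
                               columns="variable", values=value_col).reset_index()
        missing = [v for v in variables if v not in wide.columns]
        if missing:
            raise KeyError(f"variables absent from score table: {missing}")
        return cls(wide[list(variables)], wide["group"].to_numpy())

    def fit(self) -> "ManovaResults":
        x, groups = self.endog, self.groups
        n, p = x.shape
        h, e = _cross_products(x, groups)
        det_e = np.linalg.det(e)
        det_t = np.linalg.det(e + h)
        if det_e <= 0.0 or det_t <= 0.0:
            corr = np.corrcoef(x, rowvar=False)
            pairs = [
                f"{self.var_names[i]}~{self.var_names[j]}"
                for i in range(p) for j in range(i + 1, p)
                if abs(corr[i, j]) > 0.999
            ]
            raise np.linalg.LinAlgError(
                "singular within-group cross-product matrix"
                + (f"; collinear variables: {', '.join(pairs)}" if pairs else "")
            )
        lam = det_e / det_t
        df1, df2 = p, n - p - 1
        f = (df2 / df1) * (1.0 - lam) / lam
        pval = float(sps.f.sf(f, df1, df2))
        univariate = [
            (name, anova_univariate(x[:, j], groups))
            for j, name in enumerate(self.var_names)
        ]
        return ManovaResults(
            model=self,
            wilks_lambda=float(lam),
            f_stat=float(f),
            df1=df1,
            df2=df2,
            pvalue=pval,
            univariate=univariate,
            nobs=n,
        )


@dataclass(frozen=True)
class ManovaResults:
    """Fitted two-group MANOVA: multivariate test plus univariate follow-ups."""

    model: TwoGroupManova
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int
    pvalue: float
    univariate: list = field(default_factory=list)
    nobs: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.wilks_lambda <= 1.0 + 1e-12:
            raise ValueError(f"Wilks lambda {self.wilks_lambda} outside (0, 1]")
        if self.f_stat < 0:
            raise ValueError("F statistic must be non-negative")

    @property
    def significant(self) -> bool:
        return self.pvalue <= 0.05

    def summary(self) -> str:
        lines = [
            f"Two-group one-way MANOVA  (N = {self.nobs}, "
            f"{self.df1} dependent variables)",
            f"  Wilks' lambda = {self.wilks_lambda:.3f}, "
            f"F({self.df1},{self.df2}) = {self.f_stat:.2f}, "
            f"p = {self.pvalue:.3f}",
            "  Univariate follow-ups:",
        ]
        for name, res in self.univariate:
            lines.append(
                f"    {name}: F({res.df[0]},{res.df[1]}) = "
                f"{res.statistic:.2f}, p = {res.pvalue:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "wilks_lambda": self.wilks_lambda,
            "f": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.pvalue,
            "n": self.nobs,
            "univariate": [
                {"variable": name, "f": r.statistic,
                 "df1": r.df[0], "df2": r.df[1], "p": r.pvalue}
                for name, r in self.univariate
            ],
        }


def manova_family(
    score_table: pd.DataFrame,
    variables,
    value_col: str = "difference",
    prescreen_threshold: float = 0.30,
) -> dict:
    """The full family analysis: prescreen (advisory) -> MANOVA -> follow-ups.

    Returns a JSON-ready dict with the prescreen correlation summary, the
    multivariate test, the univariate follow-ups, and per-group one-tailed
    one-sample t-tests of mean change against zero.
    """
    model = TwoGroupManova.from_scores(score_table, variables, value_col)
    passed, corr, notes = intercorrelation_check(model.endog, prescreen_threshold)
    if not passed:
        warnings.warn(
            "dependent variables not all inter-correlated (|r| > "
            f"{prescreen_threshold}): {'; '.join(notes)}",
            stacklevel=2,
        )
    res = model.fit()
    ttests = {}
    for lvl in model.levels:
        sub = model.endog[model.groups == lvl]
        per_var = {}
        for j, name in enumerate(model.var_names):
            try:
                t = one_sample_t(sub[:, j], 0.0, tail="one")
                per_var[name] = {"t": t.statistic, "df": t.df[0], "p": t.pvalue}
            except ValueError as err:
                per_var[name] = {"error": str(err)}
        ttests[str(lvl)] = per_var
    return {
        "prescreen": {
            "passed": passed,
            "min_abs_r": float(np.nanmin(np.abs(
                corr[~np.eye(len(corr), dtype=bool)]))) if corr.size > 1 else None,
            "notes": notes,
        },
        "manova": res.to_dict(),
        "one_sample_t": ttests,
        "summary": res.summary(),
    }


def baseline_diagnostics(
    score_table: pd.DataFrame, variables=None
) -> pd.DataFrame:
    """Baseline-imbalance and reliability diagnostics per variable.

    For each variable: point-biserial correlation between group and the
    pre-training score, Pearson r between pre and post, and a two-sample
    t-test of group baselines.
    """
    variables = variables or sorted(score_table["variable"].unique())
    rows = []
    for var in variables:
        sub = score_table[score_table["variable"] == var].dropna(
            subset=["pre", "post"]
        )
        g = (sub["group"] == pd.unique(sub["group"])[0]).astype(int).to_numpy()
        rec = {"variable": var, "n": len(sub),
               "point_biserial_r": np.nan, "point_biserial_p": np.nan,
               "pre_post_r": np.nan, "baseline_t": np.nan, "baseline_p": np.nan}
        # correlations undefined for < 3 participants or a single group
        if len(sub) >= 3 and 0 < g.sum() < len(g):
            pre = sub["pre"].to_numpy()
            post = sub["post"].to_numpy()
            if np.std(pre) > 0:
                rpb = sps.pointbiserialr(g, pre)
                rec["point_biserial_r"] = rpb.statistic
                rec["point_biserial_p"] = rpb.pvalue
                tt = sps.ttest_ind(pre[g == 1], pre[g == 0])
                rec["baseline_t"] = tt.statistic
                rec["baseline_p"] = tt.pvalue
            if np.std(pre) > 0 and np.std(post) > 0:
                rel = sps.pearsonr(pre, post)
                rec["pre_post_r"] = rel.statistic
        rows.append(rec)
    return pd.DataFrame(rows)
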