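"""Classical group analyses on a curve-features table.

Implements the traditional arm of the analysis: per-group descriptives
(mean, sample SD), two-group comparisons (Welch's t by default — the
sex groups are unbalanced at 9 vs 22 — with Student's t behind a flag),
a two-way age x sex ANOVA with type-II sums of squares (appropriate for
the unbalanced 2x2 design), and Pearson correlation matrices with
Shapiro-Wilk normality flags per variable and stratum.

Significance is marked at p < 0.05 ("*") with a "trending" marker
("^") at p < 0.10. No multiple-testing correction is applied; reports
say so explicitly, since several dozen comparisons are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupStatsReport",
    "TwoGroupResult",
    "analyze",
    "describe",
    "two_group_test",
    "two_way_anova",
    "correlations",
    "group_differences",
    "significance_mark",
]

#: Curve-parameter columns a features table normally carries.
DEFAULT_VARIABLES = (
    "peak_N", "avg_after80_N", "rise_time_s", "rfd_N_per_s",
    "pct_above_avg", "grip_strength_N",
)

NO_CORRECTION_NOTE = (
    "p-values are unadjusted for multiple comparisons; "
    "* p<0.05, ^ p<0.10 (trending)"
)


def significance_mark(p: float) -> str:
    """'*' below 0.05, '^' below 0.10 (trending), else ''."""
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "^"
    return ""


class TwoGroupResult(NamedTuple):
    t: float
    df: float
    p: float
    group_a: str
    group_b: str


@dataclass
class GroupStatsReport:
    """Bundle of the classical analyses, mirroring the summary-table
    layout of the reference cohort report."""

    descriptives: pd.DataFrame
    t_tests: pd.DataFrame
    anova: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    normality: pd.DataFrame
    differences: pd.DataFrame | None = None
    note: str = NO_CORRECTION_NOTE

    def to_text(self) -> str:
        parts = [
            "== Descriptives (mean (SD), n) ==", self.descriptives.to_string(),
            "\n== Two-group tests ==", self.t_tests.to_string(),
            "\n== Two-way ANOVA (type II) ==", self.anova.to_string(),
        ]
        for stratum, mat in self.correlations.items():
            parts += [f"\n== Correlations [{stratum}] ==", mat.to_string()]
        parts += ["\n== Normality (Shapiro-Wilk) ==", self.normality.to_string()]
        if self.differences is not None:
            parts += ["\n== Group mean differences ==", self.differences.to_string()]
        parts += ["\n" + self.note]
        return "\n".join(parts)


def describe(
    table: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    groupings: Sequence[str] = ("age_group", "sex"),
) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per variable, overall and
    per level of each grouping column. A single-observation cell gets an
    undefined SD and a flag; an empty cell is reported missing."""
    variables = [v for v in variables if v in table.columns]
    rows = []

    def cell(frame: pd.DataFrame, grouping: str, level: str) -> None:
        for var in variables:
            vals = frame[var].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append({
                "variable": var, "grouping": grouping, "group": level, "n": n,
                "mean": vals.mean() if n else np.nan,
                "sd": vals.std(ddof=1) if n > 1 else np.nan,
                "flag": "" if n > 1 else ("single_observation" if n == 1 else "empty"),
            })

    cell(table, "all", "all")
    for grouping in groupings:
        for level, frame in table.groupby(grouping, observed=True):
            cell(frame, grouping, str(level))
    return pd.DataFrame(rows)


def two_group_test(
    table: pd.DataFrame,
    variable: str,
    grouping: str,
    *,
    equal_var: bool = False,
) -> TwoGroupResult:
    """Two-sided two-sample t-test between the two levels of ``grouping``.

    Welch's unequal-variance test by default; set ``equal_var=True`` for
    Student's pooled-variance test.
    """
    levels = sorted(table[grouping].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{grouping} must have exactly 2 levels, found {levels}")
    a = table.loc[table[grouping] == levels[0], variable].dropna().to_numpy(float)
    b = table.loc[table[grouping] == levels[1], variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.array_equal(a, b):
        # degenerate identical groups: zero variance breaks the statistic
        return TwoGroupResult(0.0, float(len(a) + len(b) - 2), 1.0,
                              str(levels[0]), str(levels[1]))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TwoGroupResult(float(res.statistic), float(res.df), float(res.pvalue),
                          str(levels[0]), str(levels[1]))


def two_way_anova(
    table: pd.DataFrame,
    variable: str,
    factors: tuple[str, str] = ("age_group", "sex"),
) -> pd.DataFrame:
    """Two-way ANOVA with type-II sums of squares.

    Returns a frame indexed by effect (two mains and the interaction)
    with columns ``F``, ``p``, ``df``, ``sum_sq``. Requires every cell
    of the 2x2 design to be non-empty.
    """
    fa, fb = factors
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs both levels present")
    counts = table.groupby([fa, fb], observed=True).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("empty cell in the 2x2 design")
    data = table[[variable, fa, fb]].dropna().rename(columns={variable: "_y"})
    model = smf.ols(f"_y ~ C({fa}) * C({fb})", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={
        f"C({fa})": fa, f"C({fb})": fb, f"C({fa}):C({fb})": f"{fa}:{fb}",
    })
    out = aov.loc[[fa, fb, f"{fa}:{fb}"], ["sum_sq", "df", "F", "PR(>F)"]]
    return out.rename(columns={"PR(>F)": "p"})


def correlations(
    table: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    by_group: str | None = "age_group",
    method: str = "pearson",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Pairwise correlations with p-values, overall and per stratum,
    plus Shapiro-Wilk normality flags per variable per stratum.

    Returns ``(matrices, normality)`` where ``matrices`` maps stratum
    name to a square DataFrame whose entries are ``(r, p)`` formatted as
    ``r`` with a significance mark, and whose ``.attrs["r"]`` /
    ``.attrs["p"]`` hold the numeric matrices.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr_fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    variables = [v for v in variables if v in table.columns]

    strata: dict[str, pd.DataFrame] = {"all": table}
    if by_group is not None:
        for level, frame in table.groupby(by_group, observed=True):
            strata[str(level)] = frame

    matrices: dict[str, pd.DataFrame] = {}
    norm_rows = []
    for name, frame in strata.items():
        k = len(variables)
        r_mat = pd.DataFrame(np.eye(k), index=variables, columns=variables)
        p_mat = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
        for va, vb in combinations(variables, 2):
            pair = frame[[va, vb]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"stratum {name!r} has n<3 complete pairs for ({va}, {vb})"
                )
            r, p = corr_fn(pair[va], pair[vb])
            r_mat.loc[va, vb] = r_mat.loc[vb, va] = float(r)
            p_mat.loc[va, vb] = p_mat.loc[vb, va] = float(p)
        display = r_mat.round(3).astype(str)
        for va in variables:
            for vb in variables:
                if va != vb:
                    display.loc[va, vb] += significance_mark(p_mat.loc[va, vb])
        display.attrs["r"] = r_mat
        display.attrs["p"] = p_mat
        matrices[name] = display
        for var in variables:
            vals = frame[var].dropna().to_numpy(float)
            if len(vals) >= 3 and np.ptp(vals) > 0:
                w, pw = sps.shapiro(vals)
                norm_rows.append({"stratum": name, "variable": var,
                                  "shapiro_W": float(w), "p": float(pw),
                                  "non_normal": pw < 0.05})
            else:
                norm_rows.append({"stratum": name, "variable": var,
                                  "shapiro_W": np.nan, "p": np.nan,
                                  "non_normal": False})
    return matrices, pd.DataFrame(norm_rows)


def group_differences(
    means: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Signed differences of group means per variable.

    Input is either ``{variable: {"male": .., "female": .., "younger":
    .., "older": ..}}`` or a :func:`describe` frame. Output columns
    state the convention: ``male_minus_female`` and
    ``younger_minus_older`` (note the sex convention flips sign for
    rise time, where females take longer to reach 80% of peak).
    """
    if isinstance(means, pd.DataFrame):
        mapping: dict[str, dict[str, float]] = {}
        for _, row in means.iterrows():
            if row["group"] in ("male", "female", "younger", "older"):
                mapping.setdefault(row["variable"], {})[row["group"]] = row["mean"]
        means = mapping
    rows = []
    for variable, groups in means.items():
        for needed in ("male", "female", "younger", "older"):
            if needed not in groups:
                raise ValueError(f"{variable}: missing stratum mean {needed!r}")
        rows.append({
            "variable": variable,
            "male_minus_female": groups["male"] - groups["female"],
            "younger_minus_older": groups["younger"] - groups["older"],
        })
    return pd.DataFrame(rows)


def analyze(
    table: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    *,
    equal_var: bool = False,
    corr_method: str = "pearson",
) -> GroupStatsReport:
    """Run the full classical battery on a features table."""
    variables = [v for v in variables if v in table.columns]
    desc = describe(table, variables)
    t_rows = []
    for grouping in ("sex", "age_group"):
        for var in variables:
            res = two_group_test(table, var, grouping, equal_var=equal_var)
            t_rows.append({
                "variable": var, "grouping": grouping,
                "group_a": res.group_a, "group_b": res.group_b,
                "t": res.t, "df": res.df, "p": res.p,
                "mark": significance_mark(res.p),
            })
    anova_rows = []
    for var in variables:
        aov = two_way_anova(table, var)
        for effect, row in aov.iterrows():
            anova_rows.append({
                "variable": var, "effect": effect, "F": row["F"],
                "df": row["df"], "p": row["p"],
                "mark": significance_mark(row["p"]),
            })
    corr, normality = correlations(table, variables, method=corr_method)
    diff_vars = [v for v in variables if v != "grip_strength_N"]
    diffs = group_differences(
        describe(table, diff_vars)
    ) if {"sex", "age_group"} <= set(table.columns) else None
    return GroupStatsReport(
        descriptives=desc,
        t_tests=pd.DataFrame(t_rows),
        anova=pd.DataFrame(anova_rows),
        correlations=corr,
        normality=normality,
        differences=diffs,
    )
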