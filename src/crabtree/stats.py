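"""Grouped comparative statistics over the yeast analysis set.

Reproduces the study-style statistical battery on the four physiology
parameters (biomass yield, ethanol yield, glucose consumption rate,
growth rate) across the four phylogenetic groups:

* one-way ANOVA (F, residual df, R^2 = SS_between/SS_total),
* Kruskal-Wallis rank test (tie-corrected H, chi-square p),
* all pairwise Welch two-sample t-tests (Welch-Satterthwaite df),
* Pearson correlation with simple OLS regression (r, R^2 = r^2,
  F with df (1, n-2)) and Spearman's rank correlation (t approximation)
  for the yield/rate trade-off pairs,
* per-group means with 95% t confidence intervals.

All tests are two-sided at alpha = 0.05.  Pairwise p-values are
reported raw (mirroring the reference analysis); an optional Holm
step-down adjustment can be applied across each parameter's six
pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import SpeciesRecord, analysis_frame

__all__ = [
    "StatReport",
    "GroupSummary",
    "one_way_anova",
    "kruskal_wallis",
    "welch_t_test",
    "pearson_regression",
    "spearman_rho",
    "group_mean_ci",
    "run_table2",
    "table2_frame",
    "TABLE2_PARAMETERS",
]

ALPHA = 0.05

#: Table column label -> analysis-frame column, in report order.
TABLE2_PARAMETERS = {
    "Biomass yield": "biomass_yield",
    "Ethanol yield": "ethanol_yield",
    "Glucose cons. rate": "glc_cons_rate",
    "Growth rate": "growth_rate",
}

#: (x, y) pairs of the correlation/regression analyses.
TABLE2_CORRELATIONS = [
    ("Glucose cons. rate", "Biomass yield"),
    ("Glucose cons. rate", "Growth rate"),
    ("Ethanol yield", "Growth rate"),
]


@dataclass(frozen=True)
class StatReport:
    """Result of one statistical test."""

    test_name: str
    parameter_x: str
    parameter_y: str
    statistic_name: str            # "F", "H", "t", "r" or "rho"
    statistic: float
    df: object                     # float, (df1, df2) pair, or None
    p_value: float
    r_squared: Optional[float] = None
    f_value: Optional[float] = None
    correlation: Optional[float] = None
    p_holm: Optional[float] = None

    @property
    def significant_at_5pct(self) -> bool:
        p = self.p_value if self.p_holm is None else self.p_holm
        return p < ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    group_id: int
    parameter: str
    n: int
    mean: float
    ci95_low: float
    ci95_high: float
    flags: tuple[str, ...] = field(default=())


def _split_groups(
    values: Sequence[float], groups: Sequence
) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    return [values[groups == g] for g in sorted(set(groups.tolist()))]


def one_way_anova(
    values: Sequence[float], groups: Sequence,
    parameter: str = "", factor: str = "Groups",
) -> StatReport:
    """Classical one-way fixed-effects ANOVA."""
    parts = _split_groups(values, groups)
    k, n = len(parts), sum(len(p) for p in parts)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if n <= k:
        raise ValueError("ANOVA needs more observations than groups")
    grand = np.concatenate(parts).mean()
    ss_between = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ss_total = float(sum(((p - grand) ** 2).sum() for p in parts))
    ss_within = ss_total - ss_between
    df1, df2 = k - 1, n - k
    if ss_within <= 0.0:
        f = 0.0 if ss_between <= 0.0 else math.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return StatReport("ANOVA", factor, parameter, "F", float(f),
                      (df1, df2), p, r_squared=float(r2), f_value=float(f))


def kruskal_wallis(
    values: Sequence[float], groups: Sequence,
    parameter: str = "", factor: str = "Groups",
) -> StatReport:
    """Kruskal-Wallis rank test with tie correction (chi-square p)."""
    parts = _split_groups(values, groups)
    if len(parts) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*parts)
    return StatReport("Kruskal-Wallis test", factor, parameter, "H",
                      float(h), float(len(parts) - 1), float(p))


def welch_t_test(
    a: Sequence[float], b: Sequence[float],
    label_a: str = "a", label_b: str = "b", parameter: str = "",
) -> StatReport:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t-test needs >= 2 observations per sample")
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0.0:
        t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    name = ("Welch Two Sample t-test"
            + (f" on {parameter}" if parameter else ""))
    return StatReport(name, label_a, label_b, "t", float(t), float(df),
                      float(p))


def pearson_regression(
    x: Sequence[float], y: Sequence[float],
    label_x: str = "x", label_y: str = "y",
) -> StatReport:
    """Pearson correlation with the matching simple OLS regression of y
    on x: R^2 = r^2 and F = r^2 (n-2) / (1-r^2) on df (1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Pearson regression needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson regression needs nonconstant x and y")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    r2 = r * r
    f = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else math.inf
    return StatReport("Pearson correlation and Regression",
                      label_x, label_y, "r", float(r), float(n - 2),
                      float(p), r_squared=float(r2), f_value=float(f),
                      correlation=float(r))


def spearman_rho(
    x: Sequence[float], y: Sequence[float],
    label_x: str = "x", label_y: str = "y",
) -> StatReport:
    """Spearman's rank correlation (tie-aware average ranks, p from the
    t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation needs nonconstant inputs")
    rho, p = sps.spearmanr(x, y)
    return StatReport("Spearman's rank correlation rho",
                      label_x, label_y, "rho", float(rho), None, float(p),
                      correlation=float(rho))


def group_mean_ci(
    values: Sequence[float], groups: Sequence,
    level: float = 0.95, parameter: str = "",
) -> list[GroupSummary]:
    """Per-group mean with a t confidence interval,
    mean +/- t_{n-1, (1+level)/2} * s / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = []
    for g in sorted(set(groups.tolist())):
        sample = values[groups == g]
        n = len(sample)
        mean = float(sample.mean())
        if n < 2:
            out.append(GroupSummary(g, parameter, n, mean, math.nan,
                                    math.nan, ("undefined CI (n=1)",)))
            continue
        half = float(sps.t.ppf(0.5 + level / 2.0, n - 1)
                     * sample.std(ddof=1) / math.sqrt(n))
        out.append(GroupSummary(g, parameter, n, mean, mean - half,
                                mean + half))
    return out


def _holm(reports: list[StatReport]) -> list[StatReport]:
    """Holm step-down adjustment over a family of reports."""
    order = sorted(range(len(reports)), key=lambda i: reports[i].p_value)
    m = len(reports)
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * reports[i].p_value)
        adjusted[i] = min(running, 1.0)
    return [
        StatReport(**{**r.__dict__, "p_holm": adjusted[i]})
        for i, r in enumerate(reports)
    ]


def run_table2(
    analysis_set: Iterable[SpeciesRecord] | pd.DataFrame,
    *, holm: bool = False,
) -> list[StatReport]:
    """Run the full grouped battery on a 37-strain analysis set:
    3 Pearson+regression rows, 3 Spearman rows, 4 ANOVA rows, 4
    Kruskal-Wallis rows and 6 pairwise Welch rows for each of the four
    parameters."""
    frame = (analysis_set if isinstance(analysis_set, pd.DataFrame)
             else analysis_frame(analysis_set))
    if "group" not in frame.columns:
        raise ValueError("analysis set lacks group assignments")
    reports: list[StatReport] = []
    for label_x, label_y in TABLE2_CORRELATIONS:
        x = frame[TABLE2_PARAMETERS[label_x]].to_numpy()
        y = frame[TABLE2_PARAMETERS[label_y]].to_numpy()
        reports.append(pearson_regression(x, y, label_x, label_y))
    for label_x, label_y in TABLE2_CORRELATIONS:
        x = frame[TABLE2_PARAMETERS[label_x]].to_numpy()
        y = frame[TABLE2_PARAMETERS[label_y]].to_numpy()
        reports.append(spearman_rho(x, y, label_x, label_y))
    groups = frame["group"].to_numpy()
    for label, column in TABLE2_PARAMETERS.items():
        reports.append(one_way_anova(frame[column].to_numpy(), groups, label))
    for label, column in TABLE2_PARAMETERS.items():
        reports.append(kruskal_wallis(frame[column].to_numpy(), groups, label))
    group_ids = sorted(set(groups.tolist()))
    for label, column in TABLE2_PARAMETERS.items():
        family: list[StatReport] = []
        for i, ga in enumerate(group_ids):
            for gb in group_ids[i + 1:]:
                a = frame.loc[frame["group"] == ga, column].to_numpy()
                b = frame.loc[frame["group"] == gb, column].to_numpy()
                family.append(
                    welch_t_test(a, b, f"Group {ga}", f"Group {gb}", label)
                )
        reports.extend(_holm(family) if holm else family)
    return reports


def table2_frame(reports: Iterable[StatReport]) -> pd.DataFrame:
    """Reports as a table mirroring the reference layout."""
    rows = []
    for r in reports:
        df = r.df
        if isinstance(df, tuple):
            df = df[1]  # residual df, as printed
        rows.append({
            "statistical_analysis": r.test_name,
            "parameter_x": r.parameter_x,
            "parameter_y": r.parameter_y,
            "significant_5pct": "Yes" if r.significant_at_5pct else "No",
            "p_value": r.p_value,
            "df": df,
            "r2": r.r_squared,
            "f_value": r.f_value,
            "correlation": r.correlation,
            "statistic_name": r.statistic_name,
            "statistic": r.statistic,
            "p_holm": r.p_holm,
        })
    return pd.DataFrame(rows)
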