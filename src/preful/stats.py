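"""Cohort statistics: normality-gated two-group tests, one-way ANOVA,
Spearman correlation matrices, and stratified summaries.

Test selection follows the conventional clinical-cohort recipe: both groups
are screened with Shapiro-Wilk; if both pass at the normality alpha an
unpaired two-sample t test is used, otherwise a two-sided Mann-Whitney U
test (exact for small tieless samples).  Summaries are mean +/- SEM
(SD/sqrt(n)).  No multiplicity adjustment is applied silently; Holm and
Benjamini-Hochberg adjusted columns can be added on request, clearly
labeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sct

from .io import SubjectRecord
from .quantify import stratify_by_vc, SEVERITY_ORDER

__all__ = [
    "GroupComparison",
    "compare_two_groups",
    "anova_oneway",
    "spearman_matrix",
    "subgroup_summary",
    "adjust_pvalues",
    "sem",
]


def sem(x: np.ndarray) -> float:
    """Standard error of the mean, SD/sqrt(n) (ddof=1); NaN for n < 2."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


@dataclass
class GroupComparison:
    metric: str
    groups: tuple[str, ...]
    test: str  # t_unpaired | mann_whitney_u | anova
    statistic: float
    p_value: float
    summaries: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _summary(name: str, x: np.ndarray) -> dict:
    return {"group": name, "n": int(x.size), "mean": float(np.mean(x)), "sem": sem(x)}


def compare_two_groups(
    x: np.ndarray,
    y: np.ndarray,
    alpha_normality: float = 0.05,
    metric: str = "",
    group_names: tuple[str, str] = ("x", "y"),
    welch: bool = False,
    force_test: str = "auto",
) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison, two-sided.

    Both samples normal at ``alpha_normality`` -> unpaired t test (pooled
    variance by default, Welch with ``welch=True``); otherwise Mann-Whitney
    U (exact when both groups have <= 8 tieless observations, normal
    approximation with tie/continuity correction otherwise).  Zero-variance
    samples bypass the normality gate straight to the nonparametric branch.
    ``force_test`` ("t" or "mannwhitney") overrides the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need n >= 3 per group for the normality gate")
    notes = [f"normality gate: Shapiro-Wilk at alpha={alpha_normality}"]

    degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
    if force_test == "t":
        normal = True
        notes.append("t test forced")
    elif force_test == "mannwhitney":
        normal = False
        notes.append("Mann-Whitney forced")
    elif force_test != "auto":
        raise ValueError(f"unknown force_test {force_test!r}")
    elif degenerate:
        warnings.warn(
            "zero-variance sample: normality gate bypassed, using Mann-Whitney U",
            stacklevel=2,
        )
        notes.append("zero-variance sample; nonparametric branch forced")
        normal = False
    else:
        pw_x = sct.shapiro(x).pvalue
        pw_y = sct.shapiro(y).pvalue
        normal = (pw_x > alpha_normality) and (pw_y > alpha_normality)

    if normal:
        res = sct.ttest_ind(x, y, equal_var=not welch)
        test = "t_unpaired"
        notes.append("Welch correction" if welch else "pooled variance")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        exact = (
            x.size <= 8
            and y.size <= 8
            and np.unique(np.concatenate([x, y])).size == x.size + y.size
        )
        method = "exact" if exact else "asymptotic"
        res = sct.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test = "mann_whitney_u"
        notes.append(f"Mann-Whitney method: {method}")
        stat, p = float(res.statistic), float(res.pvalue)
    if np.array_equal(np.sort(x), np.sort(y)) and np.ptp(x) == 0 and np.ptp(y) == 0:
        p = 1.0
    return GroupComparison(
        metric=metric,
        groups=group_names,
        test=test,
        statistic=stat,
        p_value=p,
        summaries={
            group_names[0]: _summary(group_names[0], x),
            group_names[1]: _summary(group_names[1], y),
        },
        notes=notes,
    )


def anova_oneway(
    groups: list[np.ndarray],
    group_names: list[str] | None = None,
    metric: str = "",
) -> GroupComparison:
    """One-way ANOVA across >= 3 groups (each n >= 2)."""
    if len(groups) < 3:
        raise ValueError("one-way ANOVA here needs >= 3 groups; use "
                         "compare_two_groups for two")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    names = group_names or [f"g{i}" for i in range(len(groups))]
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        stat, p = 0.0, 1.0
    else:
        res = sct.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        groups=tuple(names),
        test="anova",
        statistic=stat,
        p_value=p,
        summaries={n: _summary(n, g) for n, g in zip(names, groups)},
    )


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix.

    Symmetric with unit diagonal; average ranks for ties; cells with fewer
    than ``min_pairs`` complete pairs, or involving a constant column, are
    NaN (no-data).
    """
    num = table.select_dtypes(include=[np.number])
    rs = num.corr(method="spearman", min_periods=min_pairs)
    # constant columns: pandas can emit 0 or NaN depending on path; force NaN
    for col in num.columns:
        vals = num[col].dropna()
        if vals.size and np.ptp(vals.to_numpy()) == 0:
            rs.loc[col, :] = np.nan
            rs.loc[:, col] = np.nan
    np.fill_diagonal(rs.values, 1.0)
    for col in num.columns:
        vals = num[col].dropna()
        if vals.size and np.ptp(vals.to_numpy()) == 0:
            rs.loc[col, col] = np.nan
    return rs


def adjust_pvalues(pvals: np.ndarray, method: str = "holm") -> np.ndarray:
    """Holm or Benjamini-Hochberg adjusted p values (optional, labeled)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty_like(p)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (n - rank) * p[idx])
            adj[idx] = min(running, 1.0)
    elif method == "bh":
        prev = 1.0
        for rank in range(n - 1, -1, -1):
            idx = order[rank]
            prev = min(prev, p[idx] * n / (rank + 1))
            adj[idx] = prev
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return adj


def _stratum_of(rec: SubjectRecord, stratifier: str) -> str:
    if stratifier == "group":
        return rec.group
    if stratifier == "niv":
        if rec.group == "HV":
            return "HV"
        return "with NIV" if rec.niv else "non-NIV"
    if stratifier == "severity":
        if rec.group == "HV":
            return "HV"
        return stratify_by_vc(rec.vc_percent).label
    raise ValueError(f"unknown stratifier {stratifier!r}")


def subgroup_summary(
    records: list[SubjectRecord], stratifier: str = "severity"
) -> pd.DataFrame:
    """Per-stratum n / mean / SEM for every metric carried by the records.

    Stratum ordering is fixed: (HV, mild, moderate, severe) for severity,
    (HV, non-NIV, with NIV) for NIV status, (HV, LOPD) for group.  Empty
    strata appear with n = 0; single-subject strata report SEM as NaN.
    """
    if stratifier == "severity":
        order = ["HV", *SEVERITY_ORDER]
    elif stratifier == "niv":
        order = ["HV", "non-NIV", "with NIV"]
    elif stratifier == "group":
        order = ["HV", "LOPD"]
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")

    metrics = sorted({m for r in records for m in r.metrics})
    rows = []
    for stratum in order:
        members = [r for r in records if _stratum_of(r, stratifier) == stratum]
        if not members:
            rows.append({"stratum": stratum, "n": 0})
            continue
        row: dict = {"stratum": stratum, "n": len(members)}
        for m in metrics:
            vals = np.array([r.metrics[m] for r in members if m in r.metrics])
            if vals.size:
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_sem"] = sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)
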