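"""Group-level comparisons: Student's t-tests and chi-square spectrum tests.

Two-sided pooled-variance (Student's) t-tests compare per-line mutation
densities or recombination counts between irradiation conditions; Pearson
chi-square tests compare substitution-category counts between groups,
always on counts, never on percentages.  Welch's correction and a
Bonferroni adjustment are available behind flags but off by default.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ChiSquareResult",
    "group_summary",
    "two_sample_ttest",
    "spectrum_chisq",
    "category_vs_rest_chisq",
    "pairwise_ttest_table",
]


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Per-group aggregate: mean with its standard error over n lines."""

    group: str
    values: tuple[float, ...]
    mean: float
    se: float
    n: int


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    low_expected: bool = False


def group_summary(group: str, values: Sequence[float]) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        raise ValueError(f"group {group!r} has no values")
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return GroupSummary(group, tuple(arr), float(arr.mean()), se, n)


def two_sample_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test (pooled variance by default).

    Degenerate inputs (zero variance in both groups) give t=0, p=1 when
    the means agree and are flagged, with p=0, when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    df = (len(a) + len(b) - 2) if not welch else float("nan")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(math.inf if a.mean() > b.mean() else -math.inf,
                           0.0, df, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def spectrum_chisq(
    tables: Mapping[str, Sequence[int]] | np.ndarray,
) -> ChiSquareResult:
    """Pearson chi-square on a groups x categories contingency table.

    ``tables`` is either group -> category counts or a 2-D count array.
    Groups with a zero total are excluded with a warning; the result warns
    (via ``low_expected``) when any expected count falls below 5.
    """
    if isinstance(tables, Mapping):
        table = np.asarray(list(tables.values()), dtype=float)
        labels = list(tables)
    else:
        table = np.asarray(tables, dtype=float)
        labels = [str(i) for i in range(table.shape[0])]
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two groups")
    totals = table.sum(axis=1)
    if (totals == 0).any():
        empty = [labels[i] for i in np.nonzero(totals == 0)[0]]
        warnings.warn(f"excluding zero-total group(s): {empty}", stacklevel=2)
        table = table[totals > 0]
        if table.shape[0] < 2:
            raise ValueError("fewer than two non-empty groups remain")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        float(chi2), int(df), float(p), low_expected=bool((expected < 5).any())
    )


def category_vs_rest_chisq(
    tables: Mapping[str, Sequence[int]], category_index: int
) -> ChiSquareResult:
    """Chi-square of one substitution category against all others.

    Collapses each group's counts to (category, rest) and tests the 2 x G
    table — the per-category construction used when asking whether a
    single substitution class differs between tissues.
    """
    collapsed = {
        g: [counts[category_index], sum(counts) - counts[category_index]]
        for g, counts in tables.items()
    }
    return spectrum_chisq(collapsed)


def pairwise_ttest_table(
    values_by_group: Mapping[str, Sequence[float]],
    welch: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sample t-tests between groups, as a tidy table."""
    groups = list(values_by_group)
    rows = []
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        res = two_sample_ttest(values_by_group[a], values_by_group[b], welch=welch)
        p = res.p
        if bonferroni:
            p = min(1.0, p * len(pairs))
        rows.append(
            {"group_a": a, "group_b": b, "t": res.t, "df": res.df,
             "p": p, "degenerate": res.degenerate}
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "df", "p", "degenerate"]
    )
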