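"""Cohort-level statistics on GMFI tables.

All comparisons run on natural-log GMFI values: paired t tests for
within-group comparisons, pooled two-sample t tests for two independent
groups (Welch available), one-way ANOVA for two or more groups, and
Tukey-adjusted pairwise post hoc comparisons (Tukey-Kramer on unbalanced
groups).  All tests are two-sided with significance declared at p < .05.
Degenerate (zero-variance) inputs raise rather than silently emitting p=0/1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ALPHA",
    "TestResult",
    "DegenerateStatisticsError",
    "log_transform",
    "paired_t",
    "two_sample_t",
    "oneway_anova",
    "tukey_pairwise",
    "proportion_above_cutoff",
    "cohort_summary",
]

ALPHA = 0.05


class DegenerateStatisticsError(ValueError):
    """Inputs carry no variance (or too few observations) for the test."""


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple[str, ...]
    adjusted: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def log_transform(values) -> np.ndarray:
    """Natural log, elementwise; nonpositive input is an error."""
    v = np.asarray(values, dtype=np.float64)
    if v.size and np.any(v <= 0):
        raise ValueError("log transform requires strictly positive values")
    return np.log(v)


def _as_1d(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64).ravel()


def paired_t(log_a, log_b) -> TestResult:
    """Two-sided paired t test on log values."""
    a, b = _as_1d(log_a), _as_1d(log_b)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise DegenerateStatisticsError("need >= 2 pairs")
    if np.var(a - b, ddof=1) == 0.0:
        raise DegenerateStatisticsError("zero-variance paired differences")
    res = stats.ttest_rel(a, b)
    return TestResult(
        test="paired_t",
        statistic=float(res.statistic),
        df=(float(a.size - 1),),
        p_value=float(res.pvalue),
        groups=("a", "b"),
    )


def two_sample_t(log_a, log_b, equal_var: bool = True) -> TestResult:
    """Two-sided t test for two independent groups (pooled by default)."""
    a, b = _as_1d(log_a), _as_1d(log_b)
    if a.size < 2 or b.size < 2:
        raise DegenerateStatisticsError("each group needs >= 2 observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise DegenerateStatisticsError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        df = float(res.df)
    return TestResult(
        test="two_sample_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        df=(df,),
        p_value=float(res.pvalue),
        groups=("a", "b"),
    )


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {str(k): _as_1d(v) for k, v in groups.items()}
    if len(clean) < 2:
        raise DegenerateStatisticsError("need >= 2 groups")
    for name, v in clean.items():
        if v.size < 2:
            raise DegenerateStatisticsError(f"group {name!r} needs >= 2 observations")
    if all(np.var(v, ddof=1) == 0.0 for v in clean.values()):
        raise DegenerateStatisticsError("zero variance within every group")
    return clean


def oneway_anova(groups: dict[str, "np.ndarray"]) -> TestResult:
    """One-way ANOVA on log values across 2+ independent groups."""
    clean = _check_groups(groups)
    res = stats.f_oneway(*clean.values())
    k = len(clean)
    n = sum(v.size for v in clean.values())
    return TestResult(
        test="oneway_anova",
        statistic=float(res.statistic),
        df=(float(k - 1), float(n - k)),
        p_value=float(res.pvalue),
        groups=tuple(clean),
    )


def tukey_pairwise(groups: dict[str, "np.ndarray"]) -> pd.DataFrame:
    """Symmetric matrix of Tukey-adjusted pairwise p values.

    Uses the studentized-range (Tukey-Kramer) adjustment, valid for
    unbalanced group sizes.  The diagonal is NaN.
    """
    clean = _check_groups(groups)
    names = list(clean)
    values = np.concatenate([clean[k] for k in names])
    labels = np.concatenate([np.repeat(k, clean[k].size) for k in names])
    res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    # statsmodels enumerates pairs (i, j), i < j, over sorted unique groups
    pvals = np.asarray(res.pvalues, dtype=float)
    uniq = list(res.groupsunique)
    k = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            mat.loc[uniq[i], uniq[j]] = pvals[k]
            mat.loc[uniq[j], uniq[i]] = pvals[k]
            k += 1
    return mat


def proportion_above_cutoff(n_above: int, n_total: int) -> int:
    """Percent of cases above a cutoff, rounded half-up to an integer."""
    if n_total < 1 or not (0 <= n_above <= n_total):
        raise ValueError("require 0 <= n_above <= n_total and n_total >= 1")
    return int(math.floor(100.0 * n_above / n_total + 0.5))


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary: n, geometric mean of GMFIs, min and max.

    Expects columns ``group`` and ``gmfi``; empty groups are skipped.
    Rows are sorted by group label for stable output.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    if np.any(table["gmfi"] <= 0):
        raise ValueError("GMFI values must be positive")
    rows = []
    for group, sub in sorted(table.groupby("group"), key=lambda kv: str(kv[0])):
        g = sub["gmfi"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n": len(g),
                "geomean_gmfi": float(np.exp(np.mean(np.log(g)))),
                "min_gmfi": float(g.min()),
                "max_gmfi": float(g.max()),
            }
        )
    return pd.DataFrame(rows)
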