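import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cd9flow.cohort_stats import (
    DegenerateStatisticsError,
    cohort_summary,
    log_transform,
    oneway_anova,
    paired_t,
    proportion_above_cutoff,
    tukey_pairwise,
    two_sample_t,
)


def test_log_transform():
    np.testing.assert_allclose(log_transform([1.0, math.e]), [0.0, 1.0])
    with pytest.raises(ValueError):
        log_transform([0.0])


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_zero_variance_is_explicit_error():
    with pytest.raises(DegenerateStatisticsError):
        paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_paired_t_symmetric_differences():
    res = paired_t([1.0, 2.0], [1.5, 1.5])  # differences -0.5, +0.5
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_paired_t_matches_closed_form():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=12), rng.normal(size=12)
    res = paired_t(a, b)
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p_oracle = 2 * sps.t.sf(abs(t_oracle), len(d) - 1)
    assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
    assert res.p_value == pytest.approx(p_oracle, rel=1e-12)
    assert res.df == (11.0,)


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------

def test_two_sample_t_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = two_sample_t(g, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_two_sample_t_antisymmetric():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
    r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_growth_factor_sized_comparison_is_underpowered():
    """A 1.17-fold shift with n=8 vs 61 and sigma_log=0.4 rarely reaches p<.05.

    Mirrors the observation that a slight blast upregulation after growth
    factor was not statistically significant at those cohort sizes.
    """
    rng = np.random.default_rng(7)
    delta = math.log(1.17)
    rejections = 0
    runs = 400
    for _ in range(runs):
        a = rng.normal(math.log(1578.0) + delta, 0.4, size=8)
        b = rng.normal(math.log(1578.0), 0.4, size=61)
        if two_sample_t(a, b).p_value < 0.05:
            rejections += 1
    assert rejections / runs < 0.5  # power well below a half


# ---------------------------------------------------------------------------
# ANOVA and Tukey
# ---------------------------------------------------------------------------

def test_anova_f_equals_t_squared_at_two_groups():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 13), rng.normal(0.4, 1.3, 9)
    t = two_sample_t(a, b, equal_var=True)
    f = oneway_anova({"a": a, "b": b})
    assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
    assert f.p_value == pytest.approx(t.p_value, rel=1e-9)


def test_anova_all_constant_is_degenerate():
    with pytest.raises(DegenerateStatisticsError):
        oneway_anova({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]})


def test_anova_null_p_values_are_uniform():
    rng = np.random.default_rng(13)
    sims = 500
    pvals = np.empty(sims)
    for i in range(sims):
        groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        pvals[i] = oneway_anova(groups).p_value
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_tukey_identical_groups_p_near_one():
    g = [1.0, 2.0, 3.0, 4.0]
    mat = tukey_pairwise({"a": g, "b": g})
    assert mat.loc["a", "b"] == pytest.approx(1.0, abs=1e-6)


def test_tukey_adjusted_p_at_least_raw_p():
    rng = np.random.default_rng(17)
    groups = {
        "a": rng.normal(0, 1, 13),
        "b": rng.normal(0.5, 1, 6),
        "c": rng.normal(1.0, 1, 2),
    }
    mat = tukey_pairwise(groups)
    names = list(groups)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            raw = two_sample_t(groups[g1], groups[g2]).p_value
            assert mat.loc[g1, g2] >= raw - 1e-12
            assert mat.loc[g2, g1] == mat.loc[g1, g2]  # symmetric


def test_tukey_power_and_null_control():
    """One group shifted +1.5 log units (n=15, sigma=0.4): its pairs are
    significant in >=95% of runs; the null pair rejects in <=7%."""
    rng = np.random.default_rng(19)
    runs = 500
    hit_shifted = 0
    hit_null = 0
    for _ in range(runs):
        groups = {
            "a": rng.normal(0.0, 0.4, 15),
            "b": rng.normal(0.0, 0.4, 15),
            "c": rng.normal(1.5, 0.4, 15),
        }
        mat = tukey_pairwise(groups)
        if mat.loc["a", "c"] < 0.05 and mat.loc["b", "c"] < 0.05:
            hit_shifted += 1
        if mat.loc["a", "b"] < 0.05:
            hit_null += 1
    assert hit_shifted / runs >= 0.95
    assert hit_null / runs <= 0.07


# ---------------------------------------------------------------------------
# proportions and summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_above,n_total,expected",
    [(22, 58, 38), (9, 45, 20), (0, 10, 0), (1, 8, 13), (58, 58, 100)],
)
def test_proportion_above_cutoff_half_up(n_above, n_total, expected):
    assert proportion_above_cutoff(n_above, n_total) == expected


def test_proportion_invalid_counts():
    with pytest.raises(ValueError):
        proportion_above_cutoff(5, 4)
    with pytest.raises(ValueError):
        proportion_above_cutoff(0, 0)


def test_cohort_summary_single_sample_group():
    df = pd.DataFrame({"group": ["APL"], "gmfi": [7000.0]})
    out = cohort_summary(df)
    assert out.loc[0, "min_gmfi"] == out.loc[0, "max_gmfi"] == 7000.0
    assert out.loc[0, "n"] == 1


def test_cohort_summary_sorted_and_geomean():
    df = pd.DataFrame(
        {"group": ["b", "a", "a"], "gmfi": [100.0, 10.0, 1000.0]}
    )
    out = cohort_summary(df)
    assert list(out["group"]) == ["a", "b"]
    assert out.loc[0, "geomean_gmfi"] == pytest.approx(100.0)
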