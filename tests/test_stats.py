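"""The nonparametric test battery against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pscarbor.stats import (
    anova_bonferroni,
    cohort_table,
    ks_test,
    length_histogram,
    percent_change,
    proportion_test,
    rank_sum_test,
)
from pscarbor.types import ArborMetrics, ValidationError


def _metrics(values, genotype="g", guidance=None):
    out = []
    for i, v in enumerate(values):
        out.append(ArborMetrics(
            branch_count=int(v), total_length=float(v) * 10,
            varicosity_count=int(v), varicosities_per_branch=1.0,
            guidance_error=bool(guidance[i]) if guidance else False,
            genotype=genotype,
        ))
    return out


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def _u_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())


def _exact_p_oracle(x, y):
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_oracle(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        us.append(_u_oracle(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


def test_complete_separation_gives_zero_u():
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0


def test_identical_samples_are_not_significant():
    res = rank_sum_test([3, 1, 2], [2, 3, 1])
    assert res.p_value >= 0.9


def test_all_tied_values_are_degenerate_with_p_one():
    res = rank_sum_test([5, 5, 5], [5, 5])
    assert res.degenerate
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_small_sample_p_matches_full_enumeration(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 6, size=n).astype(float)  # ties on purpose
    y = rng.integers(0, 6, size=n).astype(float)
    if np.all(np.concatenate([x, y]) == x[0]):
        return
    res = rank_sum_test(x, y)
    assert res.method == "mann-whitney-exact"
    assert res.p_value == pytest.approx(_exact_p_oracle(x, y), abs=1e-12)


def test_exact_p_agrees_with_scipy_when_there_are_no_ties():
    rng = np.random.default_rng(11)
    x = rng.permutation(12)[:5].astype(float)
    y = (rng.permutation(12)[:5] + 0.25).astype(float)
    res = rank_sum_test(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)


def test_large_samples_use_tie_corrected_normal_approximation():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.8, 1, 25)
    res = rank_sum_test(x, y)
    assert res.method == "mann-whitney-normal"
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov
# --------------------------------------------------------------------------

def _ks_oracle(x, y):
    """Max ECDF gap by direct evaluation at every data point."""
    pts = np.concatenate([x, y])
    gaps = [abs(np.mean(x <= p) - np.mean(y <= p)) for p in pts]
    return max(gaps)


def test_identical_samples_have_zero_distance():
    res = ks_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)


def test_disjoint_supports_have_distance_one():
    res = ks_test([1, 2, 3], [10, 11, 12])
    assert res.statistic == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_d_statistic_equals_max_ecdf_gap(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, rng.integers(4, 12))
    y = rng.normal(0.5, 1.5, rng.integers(4, 12))
    res = ks_test(x, y)
    assert res.statistic == pytest.approx(_ks_oracle(x, y), abs=1e-12)


def test_tiny_samples_are_flagged_but_still_tested():
    res = ks_test([1.0, 2.0], [5.0, 6.0, 7.0])
    assert res.flags.get("small_sample")
    assert 0.0 <= res.p_value <= 1.0


# --------------------------------------------------------------------------
# chi-square on 2x2 frequencies
# --------------------------------------------------------------------------

def test_equal_proportions_give_zero_statistic():
    res = proportion_test(5, 20, 5, 20)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_no_errors_anywhere_is_degenerate():
    res = proportion_test(0, 21, 0, 21)
    assert res.degenerate


def test_statistic_matches_the_hand_computed_closed_form():
    # table: 3/20 errors vs 9/25 errors
    a, na, b, nb = 3, 20, 9, 25
    table = np.array([[a, na - a], [b, nb - b]], float)
    expected = table.sum(1, keepdims=True) @ table.sum(0, keepdims=True) / table.sum()
    stat_oracle = float(((table - expected) ** 2 / expected).sum())
    res = proportion_test(a, na, b, nb)
    assert res.statistic == pytest.approx(stat_oracle, rel=1e-12)
    ref = sps.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-12)
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_small_expected_counts_are_flagged():
    res = proportion_test(1, 5, 0, 4)
    assert res.flags.get("low_expected_counts")


# --------------------------------------------------------------------------
# ANOVA + Bonferroni
# --------------------------------------------------------------------------

def test_identical_groups_give_f_zero_and_adjusted_p_one():
    g = [[1.0, 2.0, 3.0, 4.0]] * 3
    omni, pairs = anova_bonferroni(g)
    assert omni.statistic == pytest.approx(0.0, abs=1e-12)
    assert all(p.p_value == 1.0 for p in pairs)


def test_adjusted_p_is_never_below_raw_p():
    rng = np.random.default_rng(5)
    groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.2)]
    _, pairs = anova_bonferroni(groups)
    for p in pairs:
        assert p.adjusted
        assert p.p_value >= p.flags["p_raw"] - 1e-15


def test_f_matches_the_between_within_mean_square_ratio():
    groups = [np.array([3.0, 4.0, 5.0, 6.0]),
              np.array([5.0, 6.0, 7.0, 8.0]),
              np.array([8.0, 9.0, 10.0, 11.0])]
    allv = np.concatenate(groups)
    grand = allv.mean()
    k, n = len(groups), len(allv)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
    omni, _ = anova_bonferroni(groups)
    assert omni.statistic == pytest.approx(f_oracle, rel=1e-12)


def test_zero_variance_everywhere_is_degenerate():
    omni, pairs = anova_bonferroni([[2.0, 2.0], [2.0, 2.0]])
    assert omni.degenerate
    assert all(p.degenerate for p in pairs)


# --------------------------------------------------------------------------
# percent change, summary table, histogram
# --------------------------------------------------------------------------

def test_percent_change_reproduces_published_roundings():
    pct, rounded = percent_change(1219.0, 1045.0)
    assert pct == pytest.approx(16.65, abs=0.01)
    assert rounded == 17
    pct, rounded = percent_change(918.0, 1045.0)
    assert pct == pytest.approx(-12.15, abs=0.01)
    assert abs(rounded) == 12


def test_percent_change_of_equal_values_is_zero_and_needs_positive_reference():
    assert percent_change(5.0, 5.0)[0] == 0.0
    with pytest.raises(ValidationError):
        percent_change(1.0, 0.0)


def test_cohort_table_sem_times_sqrt_n_equals_sd():
    vals = [22, 23, 25, 21, 24, 26]
    table = cohort_table({"g": _metrics(vals)})
    row = table[0]
    sd = np.std(vals, ddof=1)
    assert row.branch_mean_sem[1] * np.sqrt(len(vals)) == pytest.approx(sd, rel=1e-9)
    assert row.branch_mean_sem[0] == pytest.approx(np.mean(vals))
    assert row.n == len(vals)


def test_mean_of_two_counts_is_their_midpoint():
    table = cohort_table({"g": _metrics([22, 23])})
    assert table[0].branch_mean_sem[0] == pytest.approx(22.5)


def test_single_arbor_cohort_is_degenerate_with_zero_sem():
    table = cohort_table({"g": _metrics([22])})
    assert table[0].degenerate
    assert table[0].branch_mean_sem[1] == 0.0


def test_rows_preserve_input_order():
    cohorts = {"b": _metrics([1, 2]), "a": _metrics([3, 4]), "c": _metrics([5, 6])}
    table = cohort_table(cohorts)
    assert [r.genotype for r in table] == ["b", "a", "c"]


def test_guidance_frequency_is_the_cohort_fraction():
    table = cohort_table({"g": _metrics([1, 2, 3, 4], guidance=[1, 0, 0, 1])})
    assert table[0].guidance_error_freq == pytest.approx(0.5)


def test_identical_lengths_fall_in_a_single_bin():
    ms = _metrics([95] * 7)  # total_length 950 each
    edges, freqs = length_histogram(ms, 100.0)
    assert len(freqs) == 1
    assert edges[0] == pytest.approx(900.0)
    assert freqs[0] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(4))
def test_histogram_frequencies_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    ms = _metrics(rng.integers(50, 150, size=rng.integers(3, 30)))
    _, freqs = length_histogram(ms, 100.0)
    assert freqs.sum() == pytest.approx(1.0)
    assert (freqs >= 0).all()


def test_empty_cohort_histogram_is_an_error():
    with pytest.raises(ValidationError):
        length_histogram([], 100.0)
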