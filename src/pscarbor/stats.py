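"""Cohort statistics: the nonparametric battery and the summary table.

Conventions: all tests are two-sided; the rank-sum test uses the exact
permutation null (full enumeration) for small samples and the
tie-corrected normal approximation otherwise; the 2x2 frequency test is a
χ² without continuity correction, flagged when expected counts are small;
ANOVA post-hoc pairwise comparisons are Bonferroni-adjusted
(p_adj = min(1, m·p)).  Summary rows report mean ± SEM (SD/√n).
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ArborMetrics, CohortSummary, TestResult, ValidationError

__all__ = [
    "rank_sum_test",
    "ks_test",
    "proportion_test",
    "anova_bonferroni",
    "percent_change",
    "cohort_table",
    "cohort_table_frame",
    "length_histogram",
]

_EXACT_LIMIT = 12  # full enumeration up to n1 + n2 of this size


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (ties count 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null by enumeration of all ``C(n1+n2, n1)`` group assignments
    when n1+n2 <= 12 (handles ties exactly); tie-corrected normal
    approximation otherwise.  Two-sided exact p doubles the smaller tail
    (capped at 1).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=u, p_value=1.0, method="mann-whitney",
                          degenerate=True)
    if n1 + n2 <= _EXACT_LIMIT:
        us = []
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            us.append(_u_statistic(pooled[sel], pooled[~sel]))
        us = np.asarray(us)
        lo = np.mean(us <= u + 1e-12)
        hi = np.mean(us >= u - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(statistic=u, p_value=p, method="mann-whitney-exact")
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=u, p_value=1.0, method="mann-whitney",
                          degenerate=True)
    z = (u - mu) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=u, p_value=min(1.0, p), method="mann-whitney-normal")


def ks_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    flags = {}
    if min(len(x), len(y)) < 3:
        flags["small_sample"] = True
    return TestResult(statistic=float(res.statistic), p_value=float(min(1.0, res.pvalue)),
                      method="kolmogorov-smirnov", flags=flags)


def proportion_test(errors_a: int, n_a: int, errors_b: int, n_b: int) -> TestResult:
    """2x2 χ² test on error frequencies, without continuity correction."""
    if errors_a > n_a or errors_b > n_b or min(n_a, n_b) < 1:
        raise ValidationError("counts must satisfy errors <= n, n >= 1")
    table = np.array([[errors_a, n_a - errors_a], [errors_b, n_b - errors_b]], float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    flags = {"expected": expected.tolist()}
    if np.any(expected == 0):
        return TestResult(statistic=0.0, p_value=1.0, method="chi2",
                          degenerate=True, flags=flags)
    stat = float(np.sum((table - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    if np.any(expected < 1):
        flags["low_expected_counts"] = True
    return TestResult(statistic=stat, p_value=min(1.0, p), method="chi2", flags=flags)


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t comparisons.

    Returns ``(omnibus F test, pairwise results)``; pairwise p values are
    min(1, m·p_raw) with m the number of pairs.
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if all(np.allclose(a.var(), 0.0) for a in arrs):
        omni = TestResult(statistic=0.0, p_value=1.0, method="anova", degenerate=True)
        pairs = []
        m = len(arrs) * (len(arrs) - 1) // 2
        for i, j in itertools.combinations(range(len(arrs)), 2):
            pairs.append(TestResult(statistic=0.0, p_value=1.0, method=f"t({i},{j})",
                                    adjusted=True, degenerate=True))
        return omni, pairs
    f, p = sps.f_oneway(*arrs)
    omni = TestResult(statistic=float(f), p_value=float(min(1.0, p)), method="anova")
    m = len(arrs) * (len(arrs) - 1) // 2
    pairs = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        if np.allclose(arrs[i].var(), 0) and np.allclose(arrs[j].var(), 0):
            pairs.append(TestResult(statistic=0.0, p_value=1.0, method=f"t({i},{j})",
                                    adjusted=True, degenerate=True))
            continue
        t, praw = sps.ttest_ind(arrs[i], arrs[j])
        pairs.append(
            TestResult(statistic=float(t), p_value=float(min(1.0, m * praw)),
                       method=f"t({i},{j})", adjusted=True,
                       flags={"p_raw": float(praw)})
        )
    return omni, pairs


def percent_change(a: float, b: float) -> tuple[float, int]:
    """(100·(a−b)/b, nearest-integer rounding)."""
    if b <= 0:
        raise ValidationError("reference value must be positive")
    pct = 100.0 * (a - b) / b
    return pct, int(round(pct))


def cohort_table(
    cohorts: Mapping[str, Sequence[ArborMetrics]],
) -> list[CohortSummary]:
    """One mean ± SEM summary row per genotype, in input order."""
    out = []
    for name, metrics in cohorts.items():
        metrics = list(metrics)
        if not metrics:
            raise ValidationError(f"cohort '{name}' is empty")
        n = len(metrics)

        def mean_sem(vals):
            vals = np.asarray(vals, dtype=float)
            m = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            return (m, sem)

        out.append(
            CohortSummary(
                genotype=name,
                n=n,
                guidance_error_freq=float(np.mean([m.guidance_error for m in metrics])),
                branch_mean_sem=mean_sem([m.branch_count for m in metrics]),
                total_len_mean_sem=mean_sem([m.total_length for m in metrics]),
                varicosity_mean_sem=mean_sem([m.varicosity_count for m in metrics]),
                vpb_mean_sem=mean_sem([m.varicosities_per_branch for m in metrics]),
                degenerate=n == 1,
            )
        )
    return out


def cohort_table_frame(summaries: Iterable[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": s.genotype,
                "n": s.n,
                "guidance_error_freq": s.guidance_error_freq,
                "branch_mean": s.branch_mean_sem[0],
                "branch_sem": s.branch_mean_sem[1],
                "total_len_mean": s.total_len_mean_sem[0],
                "total_len_sem": s.total_len_mean_sem[1],
                "varicosity_mean": s.varicosity_mean_sem[0],
                "varicosity_sem": s.varicosity_mean_sem[1],
                "varicosities_per_branch_mean": s.vpb_mean_sem[0],
                "varicosities_per_branch_sem": s.vpb_mean_sem[1],
            }
            for s in summaries
        ]
    )


def length_histogram(
    cohort: Sequence[ArborMetrics], bin_width: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequencies of total arbor length in [k·bin, (k+1)·bin).

    Returns (bin left edges, frequencies summing to 1).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    vals = np.asarray([m.total_length for m in cohort], dtype=float)
    if len(vals) == 0:
        raise ValidationError("empty cohort")
    k = np.floor(vals / bin_width).astype(int)
    kmin, kmax = k.min(), k.max()
    edges = np.arange(kmin, kmax + 1) * bin_width
    freqs = np.array([(k == kk).sum() for kk in range(kmin, kmax + 1)], float)
    freqs /= freqs.sum()
    return edges, freqs
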