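"""Normality-gated group comparisons with outlier trimming.

The comparison protocol: when a sample exceeds 20 observations, the
bottom and top 2.5% (floor(0.025 n) values per tail, rank-based) are
removed before testing; each group is then gated through a Shapiro-Wilk
normality test (alpha 0.05) -- two normal groups are compared with
Student's unpaired two-sample t-test, otherwise with the Mann-Whitney U
test.  Family-wise error across multiple pairwise comparisons is
controlled by Bonferroni correction of alpha.  Three or more groups use
one-way ANOVA with post-hoc Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "trim_outliers", "compare_two", "anova_tukey"]


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, str]
    test_used: str  # t_test_unpaired | mann_whitney_u | anova_tukey
    statistic: float
    p_value: float
    family_alpha: float
    corrected_alpha: float
    n_comparisons: int
    significant: bool
    n_trimmed: tuple[int, int] = (0, 0)


def trim_outliers(
    data: np.ndarray,
    lower_frac: float = 0.025,
    upper_frac: float = 0.025,
    min_n: int = 21,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based tail trimming, applied only when n >= ``min_n``.

    Removes floor(lower_frac * n) values from the bottom and
    floor(upper_frac * n) from the top (stable ranking for ties).
    Returns (trimmed data, removed indices into the original array).
    """
    x = np.asarray(data, dtype=float)
    n = x.size
    if n < min_n:
        return x.copy(), np.array([], dtype=int)
    k_lo = int(np.floor(lower_frac * n))
    k_hi = int(np.floor(upper_frac * n))
    if k_lo == 0 and k_hi == 0:
        return x.copy(), np.array([], dtype=int)
    order = np.argsort(x, kind="stable")
    removed = np.concatenate(
        [order[:k_lo], order[n - k_hi :] if k_hi else np.array([], dtype=int)]
    )
    keep = np.setdiff1d(np.arange(n), removed)
    return x[keep], removed


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate; route to the rank test
    return stats.shapiro(x).pvalue > alpha


def compare_two(
    a: np.ndarray,
    b: np.ndarray,
    family_alpha: float = 0.05,
    n_comparisons: int = 1,
    *,
    names: tuple[str, str] = ("a", "b"),
    trim: bool = True,
    shapiro_alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample comparison with the normality gate and Bonferroni alpha.

    Trimming (when enabled and n > 20 in a group) is applied before the
    Shapiro-Wilk gate and the test itself.  ``welch=True`` substitutes
    Welch's unequal-variance t-test for the classical Student's test on
    the normal route.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    n_removed = (0, 0)
    if trim:
        a, rem_a = trim_outliers(a)
        b, rem_b = trim_outliers(b)
        n_removed = (rem_a.size, rem_b.size)
    corrected_alpha = family_alpha / n_comparisons
    if _is_normal(a, shapiro_alpha) and _is_normal(b, shapiro_alpha):
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test = "t_test_unpaired"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    p = float(res.pvalue)
    return ComparisonResult(
        groups=names,
        test_used=test,
        statistic=float(res.statistic),
        p_value=p,
        family_alpha=family_alpha,
        corrected_alpha=corrected_alpha,
        n_comparisons=n_comparisons,
        significant=p < corrected_alpha,
        n_trimmed=n_removed,
    )


def anova_tukey(
    groups: dict[str, np.ndarray],
    family_alpha: float = 0.05,
    *,
    trim: bool = True,
) -> tuple[float, float, list[ComparisonResult]]:
    """One-way ANOVA with post-hoc Tukey HSD over >= 3 groups.

    Returns (F, anova_p, pairwise results); the pairwise p-values are
    Tukey-adjusted, so they are compared directly against
    ``family_alpha`` (no further Bonferroni correction).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    names = list(groups)
    arrays = []
    for name in names:
        x = np.asarray(groups[name], dtype=float)
        if x.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 observations")
        if trim:
            x, _ = trim_outliers(x)
        arrays.append(x)
    if all(np.ptp(x) == 0 for x in arrays) and len({x[0] for x in arrays}) == 1:
        raise ValueError("degenerate: all groups constant and identical")
    f_stat, p_anova = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            results.append(
                ComparisonResult(
                    groups=(names[i], names[j]),
                    test_used="anova_tukey",
                    statistic=float(tukey.statistic[i, j]),
                    p_value=p,
                    family_alpha=family_alpha,
                    corrected_alpha=family_alpha,
                    n_comparisons=len(names) * (len(names) - 1) // 2,
                    significant=p < family_alpha,
                )
            )
    return float(f_stat), float(p_anova), results
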