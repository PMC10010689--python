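"""Two-group comparisons with the normality/variance test-selection rule.

The comparison between two groups of per-animal readouts uses an unpaired
Student t-test only when both groups pass the Shapiro–Wilk normality test
and the groups pass an F-ratio (Fisher) variance-homogeneity test; in every
other case the unpaired two-sided Mann–Whitney test is used. All
preliminary tests and the final test are two-sided at the same alpha
(0.05 by default). Significance tiers follow the usual star convention
(**** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestSelection",
    "GroupComparison",
    "choose_test",
    "compare_groups",
    "fisher_variance_test",
    "decision_from_pvalues",
    "significance_stars",
    "percent_change",
]


@dataclass
class TestSelection:
    """The three preliminary p-values and the resulting choice."""

    shapiro_p_a: float
    shapiro_p_b: float
    variance_p: float
    alpha: float
    chosen_test: str  # "unpaired-t" | "mann-whitney"


@dataclass
class GroupComparison:
    """Full record of a two-group comparison."""

    selection: TestSelection
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    alpha: float


def decision_from_pvalues(
    shapiro_p_a: float, shapiro_p_b: float, variance_p: float, alpha: float = 0.05
) -> str:
    """Pure decision rule: t-test iff all three preliminary tests pass.

    "Pass" means fail-to-reject, i.e. p > alpha.
    """
    passes = shapiro_p_a > alpha and shapiro_p_b > alpha and variance_p > alpha
    return "unpaired-t" if passes else "mann-whitney"


def fisher_variance_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-ratio test of equal variances; returns the p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:  # both degenerate: indistinguishable
        return 1.0
    if va == 0.0 or vb == 0.0:  # one degenerate: maximally heterogeneous
        return 0.0
    f = va / vb
    dist = sps.f(len(a) - 1, len(b) - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def choose_test(a, b, alpha: float = 0.05) -> TestSelection:
    """Apply Shapiro–Wilk to each group and the F variance test, then decide."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("normality testing needs n >= 3 per group")
    p_a = float(sps.shapiro(a).pvalue)
    p_b = float(sps.shapiro(b).pvalue)
    p_f = fisher_variance_test(a, b)
    return TestSelection(p_a, p_b, p_f, alpha, decision_from_pvalues(p_a, p_b, p_f, alpha))


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Run the selected two-sided test and report statistic, p and tier.

    The t-test is Student's (equal-variance) form, since the selection rule
    has already screened for variance homogeneity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sel = choose_test(a, b, alpha)
    if sel.chosen_test == "unpaired-t":
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return GroupComparison(
        selection=sel,
        statistic=float(res.statistic),
        p_value=p,
        stars=significance_stars(p),
        n_a=len(a),
        n_b=len(b),
        alpha=alpha,
    )


def percent_change(reference: float, value: float) -> float:
    """Percent by which ``value`` exceeds ``reference``: 100·(v − r)/r."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference
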