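"""Group comparisons with diagnostic-driven test selection.

Two samples are first screened with Shapiro-Wilk (normality, per sample)
and Levene (equality of variances) at alpha = 0.05.  The comparison test
is then chosen by the decision tree:

* both normal, equal variances      -> Student's t
* both normal, unequal variances    -> Welch's t
* non-normal, equal variances       -> Mann-Whitney U
* non-normal, unequal variances     -> Kolmogorov-Smirnov

All tests are two-sided; no multiple-testing correction is applied.
Correlations are Pearson product-moment with two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

ALPHA = 0.05


@dataclass(frozen=True)
class TestDecision:
    """Chosen test and the diagnostic p-values that led to it."""

    test: str                # student_t | welch_t | mann_whitney_u | kolmogorov_smirnov
    normality_p: tuple       # Shapiro-Wilk p per sample
    variance_p: float        # Levene p
    statistic: float
    p_value: float           # two-sided


def decide_test(normality_p: tuple, variance_p: float,
                alpha: float = ALPHA) -> str:
    """Pure decision function from the two diagnostic p-values."""
    normal = min(normality_p) > alpha
    equal_var = variance_p > alpha
    if normal:
        return "student_t" if equal_var else "welch_t"
    return "mann_whitney_u" if equal_var else "kolmogorov_smirnov"


def choose_test(a, b, alpha: float = ALPHA) -> TestDecision:
    """Run diagnostics on two samples and apply the selected test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InputError("each sample needs at least 3 observations")
    sh = (float(stats.shapiro(a).pvalue), float(stats.shapiro(b).pvalue))
    lev = float(stats.levene(a, b).pvalue)
    name = decide_test(sh, lev, alpha)
    if name == "student_t":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif name == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif name == "mann_whitney_u":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        res = stats.ks_2samp(a, b, alternative="two-sided")
    return TestDecision(test=name, normality_p=sh, variance_p=lev,
                        statistic=float(res.statistic),
                        p_value=float(res.pvalue))


def mean_ci(sample, confidence: float = 0.95) -> tuple:
    """Mean with a t-distribution confidence interval."""
    sample = np.asarray(sample, dtype=float)
    m = float(sample.mean())
    if len(sample) < 2:
        return m, (m, m)
    sem = stats.sem(sample)
    lo, hi = stats.t.interval(confidence, len(sample) - 1, loc=m, scale=sem)
    return m, (float(lo), float(hi))


def compare_groups(a, b, alpha: float = ALPHA) -> dict:
    """Full two-group report: chosen test, statistic, p, means with 95% CI."""
    decision = choose_test(a, b, alpha)
    mean_a, ci_a = mean_ci(a)
    mean_b, ci_b = mean_ci(b)
    return {
        "test": decision.test,
        "statistic": decision.statistic,
        "p_value": decision.p_value,
        "normality_p": decision.normality_p,
        "variance_p": decision.variance_p,
        "mean_a": mean_a, "ci_a": ci_a,
        "mean_b": mean_b, "ci_b": ci_b,
        "significant": decision.p_value < alpha,
    }


def pearson(x, y) -> tuple:
    """Pearson r with two-sided p; errors on constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("constant input: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
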