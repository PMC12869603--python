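"""Demographic/clinical comparison statistics with a normality gate.

Continuous comparisons first check Shapiro-Wilk normality (on the paired
differences, or on each sample for independent designs); normal data get a
t-test, non-normal data the rank-based analogue (Wilcoxon signed-rank or
Mann-Whitney U).  Categorical 2 x k tables use a chi-square test.  Every
result carries Cohen's d and the t-distribution 95% confidence interval of
the mean difference, which makes printed summaries reconstructible (see
:func:`t_from_summary`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .connectome import FPConnError


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float
    ci: tuple[float, float]
    n: int
    df: float


def _mean_diff_ci(diff_mean: float, se: float, df: int,
                  alpha: float) -> tuple[float, float]:
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return (diff_mean - tcrit * se, diff_mean + tcrit * se)


def compare_groups(x, y, paired: bool = False,
                   alpha: float = 0.05) -> ComparisonResult:
    """Compare two samples, choosing the test by a Shapiro-Wilk gate.

    Paired designs gate on the differences and use a paired t-test or
    Wilcoxon signed-rank; independent designs gate on each sample and use an
    independent t-test or Mann-Whitney U.  Cohen's d for paired data is the
    mean difference over the SD of differences; for independent data the
    pooled-SD standardized mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise FPConnError("need >= 3 observations per sample")
    if paired:
        if x.size != y.size:
            raise FPConnError("paired comparison requires equal lengths")
        d = x - y
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            # all differences identical; a zero difference is a degenerate
            # but well-defined outcome
            if d[0] != 0:
                raise FPConnError("zero variance of nonzero paired differences")
            return ComparisonResult("paired_t", 0.0, 1.0, 0.0, (0.0, 0.0),
                                    n, n - 1)
        normal = sps.shapiro(d).pvalue >= alpha
        se = sd / np.sqrt(n)
        ci = _mean_diff_ci(d.mean(), se, n - 1, alpha)
        effect = d.mean() / sd
        if normal:
            res = sps.ttest_rel(x, y)
            return ComparisonResult("paired_t", float(res.statistic),
                                    float(res.pvalue), float(effect), ci,
                                    n, n - 1)
        res = sps.wilcoxon(x, y)
        return ComparisonResult("wilcoxon_signed_rank", float(res.statistic),
                                float(res.pvalue), float(effect), ci, n, n - 1)
    nx, ny = x.size, y.size
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    df = nx + ny - 2
    pooled = np.sqrt(((nx - 1) * sx**2 + (ny - 1) * sy**2) / df)
    normal = (sps.shapiro(x).pvalue >= alpha) and (sps.shapiro(y).pvalue >= alpha)
    if normal and pooled == 0:
        raise FPConnError("zero variance in both samples; t-test undefined")
    se = pooled * np.sqrt(1 / nx + 1 / ny) if pooled > 0 else np.nan
    ci = (_mean_diff_ci(x.mean() - y.mean(), se, df, alpha)
          if pooled > 0 else (0.0, 0.0))
    effect = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0
    if normal:
        res = sps.ttest_ind(x, y)
        return ComparisonResult("independent_t", float(res.statistic),
                                float(res.pvalue), float(effect), ci,
                                nx + ny, df)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult("mann_whitney_u", float(res.statistic),
                            float(res.pvalue), float(effect), ci, nx + ny, df)


def chi_square_test(table) -> ComparisonResult:
    """Chi-square test of independence for a categorical contingency table."""
    table = np.asarray(table, dtype=float)
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ComparisonResult("chi_square", float(stat), float(p),
                            float(np.sqrt(stat / table.sum())),  # phi
                            (np.nan, np.nan), int(table.sum()), float(df))


def t_from_summary(mean_diff: float, ci_low: float, ci_high: float,
                   n: int) -> float:
    """Reconstruct the paired t statistic from a printed mean change and CI.

    The standard error is the CI half-width divided by the two-sided
    t critical value at n - 1 degrees of freedom; the statistic is
    |mean difference| / SE.
    """
    if not ci_low < ci_high:
        raise FPConnError("degenerate confidence interval")
    if n < 2:
        raise FPConnError("need n >= 2")
    tcrit = sps.t.ppf(0.975, n - 1)
    se = (ci_high - ci_low) / (2 * tcrit)
    return float(abs(mean_diff) / se)
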