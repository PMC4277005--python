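"""Paired agreement statistics for two body-fat estimates.

Bland-Altman limits of agreement (mean difference +/- 2 SD, the 2-SD
convention rather than 1.96), a trend regression of the difference on the
pairwise average, a paired t test, and an identity-line regression of the
reference estimate on the test estimate. The difference is oriented
test - reference throughout (here: two-component minus three-component
body fat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import InvalidInputError

__all__ = [
    "AgreementResult",
    "DegenerateStatisticWarning",
    "bland_altman",
    "paired_t",
    "identity_regression",
]


class DegenerateStatisticWarning(UserWarning):
    """A statistic is undefined on degenerate input (e.g. zero variance)."""


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement summary for paired TBF% estimates.

    ``mean_diff`` and ``sd_diff`` describe test - reference; ``limits`` are
    mean_diff +/- 2*sd_diff. The trend statistics regress the difference (y)
    on the pairwise average (x); the identity statistics regress the
    reference (y) on the test (x).
    """

    n: int
    mean_diff: float
    sd_diff: float
    limits: tuple[float, float]
    trend_r: float
    trend_p: float
    trend_slope: float
    trend_intercept: float
    paired_t_p: float
    identity_r: float
    identity_slope: float
    identity_intercept: float


def _paired(test, reference, min_n: int):
    test = np.asarray(test, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    if test.shape != reference.shape:
        raise InvalidInputError(
            f"length mismatch: {test.size} test vs {reference.size} reference"
        )
    if test.size < min_n:
        raise InvalidInputError(f"need at least {min_n} pairs, got {test.size}")
    return test, reference


def paired_t(test, reference) -> float:
    """Two-sided p-value of the paired t test on test - reference.

    Uses the t distribution with n-1 degrees of freedom. Differences with
    zero variance are degenerate: p = 1.0 when the mean difference is also
    zero (the methods are identical), otherwise NaN with a
    :class:`DegenerateStatisticWarning`.
    """
    test, reference = _paired(test, reference, min_n=2)
    diff = test - reference
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return 1.0
        warnings.warn(
            "constant non-zero differences: paired t undefined",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(stats.ttest_rel(test, reference).pvalue)


def identity_regression(test, reference) -> tuple[float, float, float]:
    """OLS of the reference estimate (y) on the test estimate (x).

    Returns (slope, intercept, Pearson r); the fit is read against the line
    of identity y = x.
    """
    test, reference = _paired(test, reference, min_n=3)
    if np.ptp(test) == 0.0:
        raise InvalidInputError("test values have zero variance; slope undefined")
    res = stats.linregress(test, reference)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bland_altman(test, reference) -> AgreementResult:
    """Bland-Altman comparison of paired TBF% estimates.

    The difference is test - reference; its SD uses the n-1 denominator and
    the limits of agreement are mean +/- 2*SD. The trend regression fits the
    difference on the pairwise average; its p-value is the OLS slope t test
    (identical to the correlation test for simple regression).
    """
    test, reference = _paired(test, reference, min_n=3)
    diff = test - reference
    avg = (test + reference) / 2.0
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))

    if np.ptp(avg) == 0.0:
        # all pairwise averages identical: trend slope undefined
        trend = (0.0, float("nan"), float("nan"), float("nan"))
    else:
        res = stats.linregress(avg, diff)
        trend = (float(res.rvalue), float(res.pvalue), float(res.slope), float(res.intercept))

    slope, intercept, r = identity_regression(test, reference)
    return AgreementResult(
        n=int(test.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        limits=(mean_diff - 2.0 * sd_diff, mean_diff + 2.0 * sd_diff),
        trend_r=trend[0],
        trend_p=trend[1],
        trend_slope=trend[2],
        trend_intercept=trend[3],
        paired_t_p=paired_t(test, reference),
        identity_r=r,
        identity_slope=slope,
        identity_intercept=intercept,
    )
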