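"""Epoch-vs-epoch descriptive comparisons (baseline-characteristics tables).

Continuous variables are compared with Welch's t-test (mean +/- sd summaries)
or the Wilcoxon rank-sum / Mann-Whitney test (median and IQR summaries);
binary variables with Pearson's chi-squared test on the 2x2 table, without
continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    summary_before: str
    summary_after: str
    test_name: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.2f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def compare_continuous(
    x, y, method: str = "welch_t", variable: str = ""
) -> ComparisonRow:
    """Two-sample comparison of a continuous variable between epochs.

    ``method`` is ``"welch_t"`` (unequal-variance t-test) or ``"rank_sum"``
    (two-sided Mann-Whitney).  Both samples must be non-empty.  Two identical
    constant samples have no evidence of a difference under the t-test, where
    the statistic is 0/0; p = 1 is returned by convention and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    if method == "welch_t":
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            logger.info(
                "compare_continuous(%s): both samples constant and equal; p=1",
                variable,
            )
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=False)
        return ComparisonRow(
            variable=variable,
            summary_before=_mean_sd(x),
            summary_after=_mean_sd(y),
            test_name="welch_t",
            statistic=float(stat),
            p_value=float(p),
        )
    if method == "rank_sum":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return ComparisonRow(
            variable=variable,
            summary_before=_median_iqr(x),
            summary_after=_median_iqr(y),
            test_name="wilcoxon_rank_sum",
            statistic=float(stat),
            p_value=float(p),
        )
    raise ValueError(f"unknown method {method!r}")


def compare_proportions(
    a: int, n1: int, c: int, n2: int, variable: str = ""
) -> ComparisonRow:
    """Pearson chi-squared test (no continuity correction) on a 2x2 table.

    ``a``/``n1`` are events/total before, ``c``/``n2`` after.  A zero margin
    (no events in either group, or events in everyone) makes the chi-squared
    statistic undefined and raises ``ValueError``.
    """
    if not (0 <= a <= n1 and 0 <= c <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("invalid 2x2 counts")
    table = np.array([[a, n1 - a], [c, n2 - c]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise ValueError(
            f"degenerate 2x2 for {variable or 'comparison'}: a zero margin "
            "leaves the chi-squared test undefined"
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonRow(
        variable=variable,
        summary_before=f"{a} ({100.0 * a / n1:.1f}%)",
        summary_after=f"{c} ({100.0 * c / n2:.1f}%)",
        test_name="chi_squared",
        statistic=float(stat),
        p_value=float(p),
    )
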