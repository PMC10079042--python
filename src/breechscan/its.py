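"""Interrupted time-series analysis of monthly undiagnosed-breech counts.

Monthly event counts are regressed on a natural cubic spline in time
(secular trend) plus an indicator for the post-policy epoch; the policy
effect is tested by comparing the models with and without the indicator —
an ANCOVA-style F-test for the default Gaussian model, a likelihood-ratio
chi-squared test for the Poisson-with-offset alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

from .cohort import BirthRecord, EpochSpec, classify_undiagnosed_breech


@dataclass(frozen=True)
class MonthlySeries:
    """Monthly bins of undiagnosed-breech counts among term breech births."""

    months: tuple[str, ...]  # "YYYY-MM", consecutive calendar months
    counts: np.ndarray  # undiagnosed breech per month
    exposure: np.ndarray  # term breech births per month
    epoch: np.ndarray  # True where the month starts on/after the cut date

    def __post_init__(self) -> None:
        n = len(self.months)
        if not (len(self.counts) == len(self.exposure) == len(self.epoch) == n):
            raise ValueError("months, counts, exposure, epoch must align")
        if (self.counts > self.exposure).any():
            raise ValueError("counts cannot exceed exposure")
        if (self.counts < 0).any() or (self.exposure < 0).any():
            raise ValueError("counts and exposure must be non-negative")

    @property
    def month_index(self) -> np.ndarray:
        return np.arange(len(self.months))


@dataclass(frozen=True)
class ITSResult:
    fitted_trend: np.ndarray  # fitted mean count per month, full model
    epoch_effect: float  # coefficient of the post-policy indicator
    f_statistic: float
    p_value: float
    spline_df: int
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "epoch_effect": self.epoch_effect,
            "statistic": self.f_statistic,
            "p_value": self.p_value,
            "spline_df": self.spline_df,
            "family": self.family,
            "fitted_trend": [float(v) for v in self.fitted_trend],
        }


def aggregate_monthly(
    records: Sequence[BirthRecord], epoch: EpochSpec
) -> MonthlySeries:
    """Bin term breech records into calendar months.

    Expects records already filtered to term breech births.  Every calendar
    month between the first and last birth appears, including months with
    zero births (explicit zero-exposure bins — no silent gaps).
    """
    if not records:
        raise ValueError("no records to aggregate")
    periods = pd.PeriodIndex(
        [pd.Period(r.birth_date, freq="M") for r in records], freq="M"
    )
    undiag = np.array([classify_undiagnosed_breech(r) for r in records])
    full = pd.period_range(periods.min(), periods.max(), freq="M")
    exposure = pd.Series(1, index=periods).groupby(level=0).sum().reindex(full, fill_value=0)
    counts = (
        pd.Series(undiag.astype(int), index=periods)
        .groupby(level=0)
        .sum()
        .reindex(full, fill_value=0)
    )
    epoch_flags = np.array(
        [epoch.is_after(p.start_time.date()) for p in full], dtype=bool
    )
    return MonthlySeries(
        months=tuple(str(p) for p in full),
        counts=counts.to_numpy(),
        exposure=exposure.to_numpy(),
        epoch=epoch_flags,
    )


def _trend_design(t: np.ndarray, df: int) -> np.ndarray:
    """Full-rank trend design of dimension df+1: constant plus a natural
    cubic spline (linear when df == 1).  The cr basis columns sum to one,
    i.e. already span the constant, so no separate intercept is stacked."""
    if df < 1:
        raise ValueError("spline_df must be >= 1")
    if df == 1:
        return np.column_stack([np.ones_like(t), t])
    return np.asarray(dmatrix("cr(t, df=df + 1) - 1", {"t": t, "df": df}))


def fit_its(
    series: MonthlySeries, spline_df: int = 4, family: str = "gaussian"
) -> ITSResult:
    """Test for a policy-associated level change against a spline trend.

    Fits counts on an intercept, a natural cubic spline in month index
    (``spline_df`` basis columns), and the post-policy indicator; the
    indicator is tested by comparing against the trend-only model.  For
    ``family="poisson"`` a log-link GLM with a log-exposure offset is used
    and the comparison is a likelihood-ratio test (zero-exposure months are
    dropped from the fit).  If the epoch indicator is constant the model
    reduces to trend-only, the epoch effect is exactly 0 and p = 1.
    """
    if family not in {"gaussian", "poisson"}:
        raise ValueError("family must be 'gaussian' or 'poisson'")
    n_before = int((~series.epoch).sum())
    n_after = int(series.epoch.sum())
    constant_epoch = n_before == 0 or n_after == 0
    if not constant_epoch and (n_before < 2 or n_after < 2):
        raise ValueError("need at least 2 months per epoch")

    t = series.month_index.astype(float)
    X_red = _trend_design(t, spline_df)
    X_full = np.column_stack([X_red, series.epoch.astype(float)])
    y = series.counts.astype(float)

    if not constant_epoch and np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            "collinear design: the epoch indicator is confounded with the "
            "spline basis; refit with fewer spline df"
        )

    if family == "poisson":
        keep = series.exposure > 0
        offset = np.log(series.exposure[keep].astype(float))
        if constant_epoch:
            fit = sm.GLM(
                y[keep], X_red[keep], family=sm.families.Poisson(), offset=offset
            ).fit()
            fitted = np.zeros_like(y)
            fitted[keep] = fit.fittedvalues
            return ITSResult(fitted, 0.0, 0.0, 1.0, spline_df, family)
        full = sm.GLM(
            y[keep], X_full[keep], family=sm.families.Poisson(), offset=offset
        ).fit()
        red = sm.GLM(
            y[keep], X_red[keep], family=sm.families.Poisson(), offset=offset
        ).fit()
        lr = 2.0 * (full.llf - red.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        fitted = np.zeros_like(y)
        fitted[keep] = full.fittedvalues
        return ITSResult(fitted, float(full.params[-1]), float(lr), p, spline_df, family)

    if constant_epoch:
        fit = sm.OLS(y, X_red).fit()
        return ITSResult(fit.fittedvalues, 0.0, 0.0, 1.0, spline_df, family)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    f_stat, p, _ = full.compare_f_test(red)
    return ITSResult(
        fitted_trend=full.fittedvalues,
        epoch_effect=float(full.params[-1]),
        f_statistic=float(f_stat),
        p_value=float(p),
        spline_df=spline_df,
        family=family,
    )
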