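"""Bivariate line fitting for log-log trait scaling.

Standardized major axis (SMA) is the symmetric line-fitting method of
choice for allometric scaling, where neither variable is a controlled
predictor.  The SMA slope is sign(r) * sd(y)/sd(x); its 95% CI and the
one-sample test of a hypothesized slope b0 use the classical result that
under the SMA model the residual axis (y - b0*x) and the fitted axis
(y + b0*x) are uncorrelated exactly when b0 is the true slope:

    slope CI:  b * (sqrt(B+1) +/- sqrt(B)),
               B = F(0.95; 1, n-2) * (1 - r^2) / (n - 2)
    slope test: t = r_rf * sqrt(df / (1 - r_rf^2)),  df = n - 2,
               r_rf = corr(y - b0*x, y + b0*x)

Ordinary least squares (with or without intercept) is provided for the
variance-partitioning models and descriptive fits.  All scaling analyses
in this package run on log10-transformed traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["LineFit", "sma_fit", "sma_fit_origin", "ols_fit"]


@dataclass(frozen=True)
class LineFit:
    """A fitted bivariate line with inference on the slope."""

    method: str  # 'sma' | 'sma_origin' | 'ols' | 'ols_through_origin'
    slope: float
    intercept: Optional[float]  # None for through-origin fits
    n: int
    r: float
    r2: float
    r2_adj: float
    ci_low: float
    ci_high: float
    hypothesized_slope: Optional[float] = None
    p_slope_test: Optional[float] = None


def _check_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def _slope_test_from_r(r_rf: float, df: int) -> float:
    """Two-sided p-value for corr(residual axis, fitted axis) = 0."""
    r_rf = float(np.clip(r_rf, -1.0, 1.0))
    if 1.0 - r_rf**2 <= 0.0:
        return 0.0
    t = r_rf * math.sqrt(df / (1.0 - r_rf**2))
    return 2.0 * stats.t.sf(abs(t), df)


def sma_fit(x, y, hypothesized_slope: Optional[float] = None) -> LineFit:
    """Standardized major axis fit of y on x (both typically log10 traits).

    Parameters
    ----------
    x, y
        Equal-length 1-D sequences, n >= 3, each with nonzero variance.
    hypothesized_slope
        If given, a two-sided one-sample test of the SMA slope against
        this value is run (df = n - 2) and reported in ``p_slope_test``.
    """
    x, y = _check_xy(x, y)
    n = len(x)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate data: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    r2 = r**2

    df = n - 2
    B = stats.f.ppf(0.95, 1, df) * (1.0 - r2) / df
    lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
    ci_low, ci_high = (lo, hi) if lo <= hi else (hi, lo)

    p = None
    if hypothesized_slope is not None:
        b0 = float(hypothesized_slope)
        resid = y - b0 * x
        fitted = y + b0 * x
        sr, sf_ = np.std(resid, ddof=1), np.std(fitted, ddof=1)
        if sr == 0.0 or sf_ == 0.0:
            # b0 is exactly the slope of perfectly collinear data
            p = 1.0
        else:
            r_rf = float(np.corrcoef(resid, fitted)[0, 1])
            p = _slope_test_from_r(r_rf, df)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LineFit(
        method="sma",
        slope=slope,
        intercept=intercept,
        n=n,
        r=r,
        r2=r2,
        r2_adj=r2_adj,
        ci_low=ci_low,
        ci_high=ci_high,
        hypothesized_slope=hypothesized_slope,
        p_slope_test=p,
    )


def sma_fit_origin(x, y, hypothesized_slope: Optional[float] = None) -> LineFit:
    """Through-origin SMA, the standard fit for independent contrasts.

    slope = sign(sum xy) * sqrt(sum y^2 / sum x^2); inference uses the
    uncentered correlation and df = n - 1 (no intercept estimated).
    Invariant to a joint sign flip of any (x_i, y_i) pair.
    """
    x, y = _check_xy(x, y, min_n=2)
    n = len(x)
    sxx = float(np.sum(x**2))
    syy = float(np.sum(y**2))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("degenerate data: all-zero x or y")
    sxy = float(np.sum(x * y))
    r = sxy / math.sqrt(sxx * syy)
    sign = -1.0 if r < 0 else 1.0
    slope = sign * math.sqrt(syy / sxx)
    r2 = r**2

    df = n - 1
    B = stats.f.ppf(0.95, 1, df) * (1.0 - r2) / df
    lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
    ci_low, ci_high = (lo, hi) if lo <= hi else (hi, lo)

    p = None
    if hypothesized_slope is not None:
        b0 = float(hypothesized_slope)
        resid = y - b0 * x
        fitted = y + b0 * x
        srr = float(np.sum(resid**2))
        sff = float(np.sum(fitted**2))
        if srr == 0.0 or sff == 0.0:
            p = 1.0
        else:
            r_rf = float(np.sum(resid * fitted) / math.sqrt(srr * sff))
            p = _slope_test_from_r(r_rf, df)
    return LineFit(
        method="sma_origin",
        slope=slope,
        intercept=None,
        n=n,
        r=r,
        r2=r2,
        r2_adj=r2,
        ci_low=ci_low,
        ci_high=ci_high,
        hypothesized_slope=hypothesized_slope,
        p_slope_test=p,
    )


def ols_fit(
    x, y, through_origin: bool = False, hypothesized_slope: Optional[float] = None
) -> LineFit:
    """Ordinary least squares fit of y on x.

    Reports plain and adjusted R^2 (adjusted with p = 1 slope).  For
    through-origin fits R^2 is the uncentered version and no intercept is
    returned.  If ``hypothesized_slope`` is given, a two-sided t-test of
    slope = b0 based on the OLS standard error is reported.
    """
    import statsmodels.api as sm

    x, y = _check_xy(x, y)
    n = len(x)
    if float(np.std(x)) == 0.0:
        raise ValueError("degenerate data: zero variance in x")
    X = x[:, None] if through_origin else sm.add_constant(x)
    model = sm.OLS(y, X).fit()
    if through_origin:
        slope = float(model.params[0])
        intercept = None
        slope_idx = 0
    else:
        intercept = float(model.params[0])
        slope = float(model.params[1])
        slope_idx = 1
    ci = model.conf_int(alpha=0.05)
    ci_low, ci_high = float(ci[slope_idx][0]), float(ci[slope_idx][1])
    r2 = float(model.rsquared)
    r2_adj = float(model.rsquared_adj)
    r = math.copysign(math.sqrt(max(r2, 0.0)), slope)
    p = None
    if hypothesized_slope is not None:
        se = float(model.bse[slope_idx])
        if se == 0.0:
            p = 1.0 if slope == hypothesized_slope else 0.0
        else:
            t = (slope - hypothesized_slope) / se
            p = 2.0 * stats.t.sf(abs(t), int(model.df_resid))
    return LineFit(
        method="ols_through_origin" if through_origin else "ols",
        slope=slope,
        intercept=intercept,
        n=n,
        r=r,
        r2=r2,
        r2_adj=r2_adj,
        ci_low=ci_low,
        ci_high=ci_high,
        hypothesized_slope=hypothesized_slope,
        p_slope_test=p,
    )
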