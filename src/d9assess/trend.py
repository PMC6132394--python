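"""Temporal trend machinery for annual monitoring series.

The workhorse is a locally weighted linear smoother (LOESS) with a fixed
window width expressed in years, not in points: the fit at target year t is
a weighted least-squares line over the observations within t +/- width/2,
with tricube weights in the scaled distance.  Because each fitted value is a
fixed linear combination of the observations, the smoother has an explicit
hat matrix L (fit = L y), which carries all downstream inference:

* an ANOVA in the style of Fryer & Nicholson decomposes the trend into a
  linear component (mean vs straight line) and a non-linear component
  (straight line vs smoother), with smoother degrees of freedom taken as
  trace(L) (first-order approximation; the two-trace correction
  df = 2 tr(L) - tr(L L') is a known refinement not used here);
* a contrast test compares the smoothed values at two years at least
  seven years apart, using the hat rows to propagate the residual variance.

A plain least-squares line supplies the reported trend-line endpoints; on
declining series the line may cross zero before the final year, in which
case the calculated endpoint is reported as "not detected".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .datamodel import TimeSeries
from .errors import InsufficientDataError

DEFAULT_WINDOW_YEARS = 7.0
MIN_CONTRAST_SPAN_YEARS = 7.0


# ---------------------------------------------------------------------------
# local linear smoother


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - np.abs(u[inside]) ** 3) ** 3
    return w


def _uniform(u: np.ndarray) -> np.ndarray:
    return (np.abs(u) <= 1.0).astype(float)


_KERNELS = {"tricube": _tricube, "uniform": _uniform}


def _half_widths(years: np.ndarray, targets: np.ndarray, half_window: float, min_points: int = 3
                 ) -> np.ndarray:
    """Per-target half-width: the nominal half window, symmetrically widened
    to the ``min_points``-th nearest observation when the window holds fewer
    than ``min_points`` points (keeps every local fit solvable)."""
    dist = np.abs(targets[:, None] - years[None, :])
    counts = (dist <= half_window).sum(axis=1)
    kth = np.sort(dist, axis=1)[:, min_points - 1]
    # nudge so the widened boundary point keeps a positive tricube weight
    widened = kth * (1.0 + 1e-9) + 1e-12
    return np.where(counts >= min_points, half_window, widened)


def _hat_rows(years: np.ndarray, targets: np.ndarray, half_window: float, kernel: str
              ) -> np.ndarray:
    """Hat rows of the local linear fit at each target year.

    Row i gives coefficients l such that fitted(target_i) = l . y for any
    observation vector y; rows sum to 1 (local lines reproduce constants).
    """
    kfun = _KERNELS[kernel]
    h = _half_widths(years, targets, half_window)
    x = years[None, :] - targets[:, None]          # centred abscissae
    w = kfun(x / h[:, None])
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    denom = sw * swxx - swx**2
    rows = np.empty_like(w)
    for i in range(len(targets)):
        if denom[i] > 1e-12 * max(sw[i] * swxx[i], 1e-300):
            rows[i] = w[i] * (swxx[i] - swx[i] * x[i]) / denom[i]
        else:
            # all usable weight on one abscissa: fall back to weighted mean
            rows[i] = w[i] / sw[i]
    return rows


@dataclass
class SmootherFit:
    """A fitted local linear smoother with its hat matrix.

    ``hat_rows[i]`` are the weights producing ``fitted[i]`` from the
    observations; ``residual_df = n - trace(hat)`` and ``sigma2`` is the
    residual variance RSS / residual_df (0 for an exact fit).
    """

    years: np.ndarray
    values: np.ndarray
    fitted: np.ndarray
    hat_rows: np.ndarray
    window_years: float
    kernel: str
    residual_df: float
    sigma2: float

    @property
    def rss(self) -> float:
        return float(np.sum((self.values - self.fitted) ** 2))

    @property
    def model_df(self) -> float:
        return float(np.trace(self.hat_rows))

    def hat_row_at(self, year: float) -> np.ndarray:
        """Hat row for the smoothed value at an arbitrary year in range."""
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValueError(f"year {year} outside fitted range {self.years[0]}-{self.years[-1]}")
        return _hat_rows(
            self.years, np.asarray([float(year)]), self.window_years / 2.0, self.kernel
        )[0]

    def predict(self, year: float) -> float:
        return float(self.hat_row_at(year) @ self.values)


def loess_fit_arrays(
    years: np.ndarray,
    values: np.ndarray,
    window_years: float = DEFAULT_WINDOW_YEARS,
    kernel: str = "tricube",
    min_points: int = 5,
) -> SmootherFit:
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < min_points:
        raise InsufficientDataError(
            f"smoother needs >= {min_points} points, got {len(years)}"
        )
    if window_years <= 0:
        raise ValueError("window_years must be > 0")
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {sorted(_KERNELS)}")
    rows = _hat_rows(years, years, window_years / 2.0, kernel)
    fitted = rows @ values
    model_df = float(np.trace(rows))
    residual_df = len(years) - model_df
    rss = float(np.sum((values - fitted) ** 2))
    sigma2 = rss / residual_df if residual_df > 0 else 0.0
    return SmootherFit(
        years=years,
        values=values,
        fitted=fitted,
        hat_rows=rows,
        window_years=window_years,
        kernel=kernel,
        residual_df=residual_df,
        sigma2=sigma2,
    )


def loess_fit(
    series: TimeSeries,
    window_years: float = DEFAULT_WINDOW_YEARS,
    kernel: str = "tricube",
    censored_substitution: str = "loq",
) -> SmootherFit:
    """Fit the fixed-window LOESS smoother to a monitoring series."""
    return loess_fit_arrays(
        np.asarray(series.years, dtype=float),
        np.asarray(series.fit_values(censored_substitution), dtype=float),
        window_years=window_years,
        kernel=kernel,
    )


# ---------------------------------------------------------------------------
# trend ANOVA (mean vs line vs smoother)


@dataclass
class TrendTestResult:
    """Linear and non-linear trend components of one series."""

    F_linear: float
    p_linear: float
    F_nonlinear: Optional[float]
    p_nonlinear: Optional[float]
    slope: float
    overall_trend: str  # "decreasing" | "increasing" | "none"
    alpha: float
    n: int
    smoother_df: float


def trend_anova_arrays(
    years: np.ndarray,
    values: np.ndarray,
    window_years: float = DEFAULT_WINDOW_YEARS,
    alpha: float = 0.05,
    kernel: str = "tricube",
) -> TrendTestResult:
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(years)
    if n < 7:
        raise InsufficientDataError(f"trend ANOVA needs >= 7 points, got {n}")

    fit = loess_fit_arrays(years, values, window_years=window_years, kernel=kernel)
    rss0 = float(np.sum((values - values.mean()) ** 2))
    slope, intercept = np.polyfit(years, values, 1)
    rss1 = float(np.sum((values - (slope * years + intercept)) ** 2))
    rss2 = fit.rss
    df2 = fit.model_df
    resid_df = n - df2
    denom = rss2 / resid_df if resid_df > 0 else np.nan

    if denom > 0:
        F_lin = ((rss0 - rss1) / 1.0) / denom
        p_lin = float(stats.f.sf(F_lin, 1, resid_df))
    else:  # exact smoother fit: a line through the data is a perfect trend
        F_lin = np.inf if rss0 > rss1 else 0.0
        p_lin = 0.0 if rss0 > rss1 else 1.0

    if df2 > 2 and denom > 0:
        F_nonlin = ((rss1 - rss2) / (df2 - 2.0)) / denom
        F_nonlin = max(F_nonlin, 0.0)  # guard tiny negative from round-off
        p_nonlin = float(stats.f.sf(F_nonlin, df2 - 2.0, resid_df))
    else:
        F_nonlin = None
        p_nonlin = None

    if p_lin <= alpha:
        overall = "decreasing" if slope < 0 else "increasing"
    else:
        overall = "none"
    return TrendTestResult(
        F_linear=float(F_lin),
        p_linear=p_lin,
        F_nonlinear=None if F_nonlin is None else float(F_nonlin),
        p_nonlinear=p_nonlin,
        slope=float(slope),
        overall_trend=overall,
        alpha=alpha,
        n=n,
        smoother_df=df2,
    )


def trend_anova(
    series: TimeSeries,
    window_years: float = DEFAULT_WINDOW_YEARS,
    alpha: float = 0.05,
    kernel: str = "tricube",
    censored_substitution: str = "loq",
) -> TrendTestResult:
    """Decompose a series' trend into linear and non-linear components.

    Three nested fits — overall mean (M0), straight line (M1), LOESS
    smoother (M2) — give the variance decomposition; the smoother's model
    degrees of freedom are trace of its hat matrix.  F statistics:

        F_linear    = (RSS0 - RSS1) / (RSS2 / (n - df2))
        F_nonlinear = (RSS1 - RSS2)/(df2 - 2) / (RSS2 / (n - df2))

    If the smoother is no rougher than a line (df2 <= 2) the non-linear
    component is not applicable and reported as None.
    """
    return trend_anova_arrays(
        np.asarray(series.years, dtype=float),
        np.asarray(series.fit_values(censored_substitution), dtype=float),
        window_years=window_years,
        alpha=alpha,
        kernel=kernel,
    )


# ---------------------------------------------------------------------------
# contrast test between two time points


@dataclass
class ContrastResult:
    difference: float
    se: float
    t: float
    p: float
    year_a: float
    year_b: float


def contrast_test(
    fit: SmootherFit,
    year_a: float,
    year_b: float,
    min_span_years: float = MIN_CONTRAST_SPAN_YEARS,
) -> ContrastResult:
    """Test the difference between smoothed values at two years.

    Refuses spans shorter than ``min_span_years`` (default seven years, the
    assessment convention — differences over shorter spans are dominated by
    the smoother's local noise).  The difference's standard error follows
    from the hat rows: Var = sigma2 * ||l_b - l_a||^2, with a t reference
    on the smoother's residual degrees of freedom.
    """
    if abs(year_b - year_a) < min_span_years:
        raise ValueError(
            f"contrast span {abs(year_b - year_a):g} years is below the "
            f"minimum of {min_span_years:g} years"
        )
    row_a = fit.hat_row_at(year_a)
    row_b = fit.hat_row_at(year_b)
    diff = float((row_b - row_a) @ fit.values)
    se = float(np.sqrt(fit.sigma2 * np.sum((row_b - row_a) ** 2)))
    if fit.residual_df <= 0:
        raise InsufficientDataError("no residual degrees of freedom for the contrast test")
    if se == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), fit.residual_df))
    return ContrastResult(difference=diff, se=se, t=float(t), p=p,
                          year_a=year_a, year_b=year_b)


# ---------------------------------------------------------------------------
# linear trend endpoints


@dataclass
class LinearTrendResult:
    """Least-squares line through a series with reported endpoints.

    ``calc_first``/``calc_last`` are the line's values at the first and last
    sampling years.  A negative ``calc_last`` means the fitted line has
    crossed zero — the trend-line concentration in the final year is then
    reported as not detected and the percent change is not applicable.
    ``calc_vs_measured_factor`` = max/min of calculated vs measured final
    value flags years the trend line does not represent well.
    """

    slope: float
    intercept: float
    p_slope: float
    calc_first: float
    calc_last: float
    percent_change: Optional[float]
    last_year_status: str  # "value" | "not_detected"
    measured_last: float
    calc_vs_measured_factor: Optional[float]
    year_first: int
    year_last: int


def linear_trend(series: TimeSeries, censored_substitution: str = "loq") -> LinearTrendResult:
    years = np.asarray(series.years, dtype=float)
    values = np.asarray(series.fit_values(censored_substitution), dtype=float)
    if len(years) < 3:
        raise InsufficientDataError(f"linear trend needs >= 3 points, got {len(years)}")
    res = stats.linregress(years, values)
    calc_first = float(res.slope * years[0] + res.intercept)
    calc_last = float(res.slope * years[-1] + res.intercept)
    measured_last = float(values[-1])
    if calc_last < 0:
        status = "not_detected"
        pct = None
        factor = None
    else:
        status = "value"
        pct = (
            100.0 * (calc_last - calc_first) / calc_first if calc_first != 0 else None
        )
        if calc_last > 0 and measured_last > 0:
            factor = max(calc_last, measured_last) / min(calc_last, measured_last)
        else:
            factor = None
    return LinearTrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue) if not np.isnan(res.pvalue) else 1.0,
        calc_first=calc_first,
        calc_last=calc_last,
        percent_change=pct,
        last_year_status=status,
        measured_last=measured_last,
        calc_vs_measured_factor=factor,
        year_first=int(series.years[0]),
        year_last=int(series.years[-1]),
    )
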