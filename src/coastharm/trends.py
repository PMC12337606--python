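"""Long-term trend estimation on deseasonalized anomalies.

A linear trend ``anomaly = b0 + b1 * t_years`` is estimated by
generalized least squares with an AR(1) error model: an OLS pass
estimates the lag-1 autocorrelation of the residuals on the observation
sequence, then the model is refitted under that covariance (two-stage,
iterated once).  Trends from several sites are pooled as an arithmetic
mean with the per-site slope standard errors propagated assuming
independent regressions.  Seasonal-cycle change over a record is probed
by splitting it at its temporal midpoint, fitting the harmonic model to
each half, and differencing the harmonic elements (dates differenced on
the circle); element shifts across groups of sites are compared with
Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonics import (
    YEAR_DAYS,
    CompositeSummary,
    HarmonicFit,
    circular_delta,
    composite_extrema,
    fit_harmonics,
    to_climatology,
)
from .series import SampleSeries

SIGNIFICANCE_LEVEL = 0.05
DAYS_PER_YEAR = 365.25


@dataclass
class TrendResult:
    slope: float          # units per year
    slope_se: float
    p_value: float
    ar1_rho_hat: float
    n_obs: int
    span_years: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "slope_se": self.slope_se,
            "p_value": self.p_value, "ar1_rho_hat": self.ar1_rho_hat,
            "n_obs": self.n_obs, "span_years": self.span_years,
            "significant_at_0.05": self.significant,
        }


@dataclass
class SplitHalfResult:
    fit_early: HarmonicFit
    fit_late: HarmonicFit
    comp_early: CompositeSummary
    comp_late: CompositeSummary
    deltas: dict[str, float]      # late minus early, dates circular
    midpoint: pd.Timestamp
    n_early: int
    n_late: int


def _time_years(times: pd.DatetimeIndex) -> np.ndarray:
    return np.asarray((times - times[0]) / pd.Timedelta(days=DAYS_PER_YEAR))


def gls_trend(anomalies: SampleSeries, min_span_years: float = 3.0) -> TrendResult:
    """AR(1)-GLS linear trend of a deseasonalized anomaly series.

    Two-stage: OLS residuals give the lag-1 autocorrelation estimate
    (on the observation sequence, appropriate for near-regular
    low-frequency records), then a single GLS refit under the AR(1)
    covariance yields the slope, its SE and a two-sided p-value.
    """
    n = len(anomalies)
    if n < 12:
        raise ValueError(f"trend estimation needs >= 12 observations, got {n}")
    span = anomalies.span_years
    if span < min_span_years:
        raise ValueError(f"trend estimation needs >= {min_span_years} years, got {span:.2f}")
    t = _time_years(anomalies.times)
    if np.ptp(t) == 0:
        raise ValueError("degenerate time design: all observations at one time")
    X = sm.add_constant(t)
    # GLSAR with maxiter=2: OLS fit, rho from residual lag-1 autocorrelation,
    # one GLS refit -- the two-stage estimator.
    model = sm.GLSAR(anomalies.values, X, rho=1)
    res = model.iterative_fit(maxiter=2)
    rho_hat = float(np.clip(model.rho[0], -0.999, 0.999))
    return TrendResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        ar1_rho_hat=rho_hat,
        n_obs=n,
        span_years=float(span),
    )


def ols_trend(anomalies: SampleSeries) -> TrendResult:
    """Plain OLS trend (no autocorrelation correction), for comparison."""
    t = _time_years(anomalies.times)
    X = sm.add_constant(t)
    res = sm.OLS(anomalies.values, X).fit()
    r = res.resid
    rho = float(np.corrcoef(r[:-1], r[1:])[0, 1]) if len(r) > 2 else 0.0
    return TrendResult(
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]), ar1_rho_hat=rho,
        n_obs=len(anomalies), span_years=float(anomalies.span_years),
    )


def pool_trends(site_trends: list[TrendResult]) -> tuple[float, float]:
    """Multi-site mean trend with propagated SE.

    mean = arithmetic mean of slopes; SE = sqrt(sum se_i^2) / m,
    assuming the per-site regressions are independent.
    """
    if not site_trends:
        raise ValueError("no trends to pool")
    slopes = np.array([t.slope for t in site_trends])
    ses = np.array([t.slope_se for t in site_trends])
    m = len(site_trends)
    return float(slopes.mean()), float(np.sqrt(np.sum(ses**2)) / m)


def split_half_shift(series: SampleSeries, K: int = 2,
                     min_span_years: float = 10.0) -> SplitHalfResult:
    """Harmonic-element shifts between the two halves of a record.

    The record is split at its temporal midpoint; the harmonic model
    and composite extrema are fitted to each half, and late-minus-early
    deltas are formed for every element (date elements on the circle,
    reported in (-period/2, period/2]).
    """
    if series.span_years < min_span_years:
        raise ValueError(
            f"split-half analysis needs >= {min_span_years} years, "
            f"got {series.span_years:.1f}"
        )
    midpoint = series.times[0] + (series.times[-1] - series.times[0]) / 2
    early = series.select(np.asarray(series.times <= midpoint))
    late = series.select(np.asarray(series.times > midpoint))
    halves = {}
    for name, half in (("early", early), ("late", late)):
        try:
            fit = fit_harmonics(to_climatology(half), K=K)
        except ValueError as exc:
            raise ValueError(f"{name} half has insufficient seasonal coverage: {exc}")
        halves[name] = (fit, composite_extrema(fit))
    fit_e, comp_e = halves["early"]
    fit_l, comp_l = halves["late"]
    deltas: dict[str, float] = {}
    for key in fit_e.elements():
        e, l = fit_e.elements()[key], fit_l.elements()[key]
        if key.startswith("date"):
            k = int(key.rsplit("_", 1)[1])
            deltas[key] = circular_delta(l, e, period=YEAR_DAYS / k)
        else:
            deltas[key] = l - e
    for key in comp_e.elements():
        e, l = comp_e.elements()[key], comp_l.elements()[key]
        if key.startswith("date"):
            deltas[key] = circular_delta(l, e)
        else:
            deltas[key] = l - e
    return SplitHalfResult(
        fit_early=fit_e, fit_late=fit_l, comp_early=comp_e, comp_late=comp_l,
        deltas=deltas, midpoint=midpoint, n_early=len(early), n_late=len(late),
    )


def group_ttests(group_a: list[SplitHalfResult],
                 group_b: list[SplitHalfResult]) -> pd.DataFrame:
    """Welch two-sample t-tests comparing element shifts across site groups.

    Each row is one harmonic/composite element; columns give the group
    mean deltas, the t statistic and the two-sided p-value.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    keys = group_a[0].deltas.keys()
    rows = []
    for key in keys:
        a = np.array([r.deltas[key] for r in group_a])
        b = np.array([r.deltas[key] for r in group_b])
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "element": key, "mean_delta_a": a.mean(), "mean_delta_b": b.mean(),
            "t_stat": float(t), "p_value": float(p),
        })
    return pd.DataFrame(rows)


def one_group_ttest(results: list[SplitHalfResult]) -> pd.DataFrame:
    """One-sample t-test per element: is the mean shift across sites nonzero?"""
    if not results:
        raise ValueError("no results")
    rows = []
    for key in results[0].deltas:
        d = np.array([r.deltas[key] for r in results])
        if len(d) > 1 and d.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(d, 0.0)
        else:
            t, p = np.nan, np.nan
        rows.append({"element": key, "mean_delta": d.mean(),
                     "t_stat": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)


def trend_table(results: dict[tuple[str, str], TrendResult]) -> pd.DataFrame:
    """Tidy per-(site, variable) trend table with significance flags."""
    rows = []
    for (site, variable), r in results.items():
        rows.append({"site": site, "variable": variable, **r.to_dict()})
    return pd.DataFrame(rows)
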