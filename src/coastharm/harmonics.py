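"""Two-harmonic climatological model of the seasonal cycle.

The seasonal climatology of a variable y at day-of-year t is modelled as

    y^m(t) = ybar + sum_{k=1..K} [ a_k cos(2 pi k t / 365) + b_k sin(2 pi k t / 365) ]

fitted by ordinary least squares on all individual observations mapped
to a 365-day climatological calendar.  k = 1 is the annual harmonic,
k = 2 the semi-annual; K = 2 by default.  Each harmonic is summarised
by its amplitude C_k = sqrt(a_k^2 + b_k^2), phase phi_k = atan2(b_k, a_k)
and date of maximum (365 / (2 pi k)) * phi_k mapped into (0, 365].

The composite curve (mean plus both harmonics) is characterised by the
zero-points of its time derivative: global maximum and minimum dates
and values, and the composite seasonal amplitude, defined as half the
max-minus-min range.  Confidence intervals for every element come from
a case-resampling bootstrap.  Deviations of observations from the
fitted curve are the deseasonalized anomalies used for trend detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .series import SampleSeries

YEAR_DAYS = 365.0

__all__ = [
    "ClimatologySeries",
    "HarmonicFit",
    "CompositeSummary",
    "BootstrapCI",
    "day_of_year_365",
    "to_climatology",
    "fit_harmonics",
    "variance_fractions",
    "composite_extrema",
    "bootstrap_fit",
    "reduced_chi_squared",
    "deseasonalize",
    "circular_delta",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class ClimatologySeries:
    """Observations mapped onto a 365-day climatological calendar."""

    day_of_year: np.ndarray  # float in [1, 365]
    values: np.ndarray
    times: pd.DatetimeIndex | None = None
    site: str = ""
    variable: str = ""

    def __post_init__(self) -> None:
        self.day_of_year = np.asarray(self.day_of_year, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.day_of_year.shape != self.values.shape:
            raise ValueError("day_of_year and values must have equal length")
        if len(self.day_of_year) and (
            self.day_of_year.min() < 1 or self.day_of_year.max() > YEAR_DAYS
        ):
            raise ValueError("day_of_year outside [1, 365]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class HarmonicFit:
    """OLS fit of the K-harmonic seasonal model and its derived elements."""

    mean: float
    cos_coef: np.ndarray  # a_k, length K
    sin_coef: np.ndarray  # b_k, length K
    amplitude: np.ndarray  # C_k
    phase: np.ndarray  # phi_k, radians
    date_of_max: np.ndarray  # day of year of each harmonic's peak, in (0, 365/k]
    var_fraction: np.ndarray  # fraction of total sample variance per harmonic
    total_var_captured: float
    resid_sd: float
    red_chisq: float
    n_obs: int
    K: int = 2

    @property
    def dominant_harmonic(self) -> int:
        """1-based index of the harmonic with the largest amplitude."""
        return int(np.argmax(self.amplitude)) + 1

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted curve at day-of-year ``t`` (may be fractional)."""
        t = np.asarray(t, dtype=float)
        y = np.full(t.shape, self.mean)
        for k in range(1, self.K + 1):
            w = 2.0 * np.pi * k * t / YEAR_DAYS
            y = y + self.cos_coef[k - 1] * np.cos(w) + self.sin_coef[k - 1] * np.sin(w)
        return y

    def derivative(self, t: np.ndarray | float) -> np.ndarray | float:
        """d y^m / dt at day-of-year ``t``."""
        t = np.asarray(t, dtype=float)
        dy = np.zeros(t.shape)
        for k in range(1, self.K + 1):
            wk = 2.0 * np.pi * k / YEAR_DAYS
            dy = dy + wk * (
                -self.cos_coef[k - 1] * np.sin(wk * t)
                + self.sin_coef[k - 1] * np.cos(wk * t)
            )
        return dy

    def elements(self) -> dict[str, float]:
        d = {"mean": self.mean}
        for k in range(1, self.K + 1):
            d[f"C{k}"] = float(self.amplitude[k - 1])
            d[f"date_of_max_{k}"] = float(self.date_of_max[k - 1])
        return d


@dataclass
class CompositeSummary:
    """Extrema of the composite (mean + all harmonics) seasonal curve."""

    date_of_max: float
    date_of_min: float
    value_at_max: float
    value_at_min: float
    composite_amplitude: float
    degenerate: bool = False  # flat curve: dates undefined
    multiple_maxima: bool = False
    multiple_minima: bool = False

    def elements(self) -> dict[str, float]:
        return {
            "date_of_max": self.date_of_max,
            "date_of_min": self.date_of_min,
            "value_at_max": self.value_at_max,
            "value_at_min": self.value_at_min,
            "composite_amplitude": self.composite_amplitude,
        }


@dataclass
class BootstrapCI:
    """Percentile bootstrap intervals for every fit/composite element."""

    intervals: dict[str, tuple[float, float]]
    point: dict[str, float]
    n_boot: int
    level: float
    seed: int | None
    samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def contains(self, element: str, value: float) -> bool:
        lo, hi = self.intervals[element]
        if element.startswith("date"):
            # compare on the circle, unwrapped around the point estimate
            period = _element_period(element)
            value = _unwrap(np.asarray([value]), self.point[element], period)[0]
        return lo <= value <= hi

    def width(self, element: str) -> float:
        lo, hi = self.intervals[element]
        return hi - lo


# ---------------------------------------------------------------------------
# day-of-year convention

def day_of_year_365(times: pd.DatetimeIndex) -> np.ndarray:
    """Map timestamps to a 1..365 climatological day of year.

    Leap years are squeezed onto the 365-day calendar: Feb 29 shares
    day 60 with Mar 1, and later days keep their non-leap-year number
    (Dec 31 is always day 365).
    """
    times = pd.DatetimeIndex(times)
    doy = times.dayofyear.to_numpy().astype(float)
    leap = times.is_leap_year
    late = leap & (doy > 60)
    doy[late] -= 1
    return doy


def to_climatology(series: SampleSeries) -> ClimatologySeries:
    """Compile a series into climatological day-of-year form."""
    if len(series) == 0:
        raise ValueError("empty series")
    return ClimatologySeries(
        day_of_year=day_of_year_365(series.times),
        values=series.values,
        times=series.times,
        site=series.site,
        variable=series.variable,
    )


# ---------------------------------------------------------------------------
# fitting

def _design_matrix(t: np.ndarray, K: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, K + 1):
        w = 2.0 * np.pi * k * t / YEAR_DAYS
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def _date_of_max(phase: float, k: int) -> float:
    """Peak day of harmonic k from its phase, mapped into (0, 365/k]."""
    period = YEAR_DAYS / k
    d = (YEAR_DAYS / (2.0 * np.pi * k)) * phase
    d = d % period
    if d <= 0.0:
        d += period
    return d


def fit_harmonics(clim: ClimatologySeries, K: int = 2,
                  sigma: float | None = None) -> HarmonicFit:
    """OLS fit of the K-harmonic seasonal model to a climatology.

    Requires at least 2K+1 distinct day-of-year values; ``sigma`` is the
    per-observation measurement SD used for the reduced chi-squared
    (defaults to the residual SD, which makes the statistic ~1 by
    construction).
    """
    t = clim.day_of_year
    y = clim.values
    n = len(y)
    p = 2 * K + 1
    if len(np.unique(t)) < p:
        raise ValueError(
            f"need >= {p} distinct day-of-year values for K={K}; "
            f"got {len(np.unique(t))}"
        )
    X = _design_matrix(t, K)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    a = beta[1::2]
    b = beta[2::2]
    amp = np.hypot(a, b)
    phase = np.arctan2(b, a)
    dates = np.array([_date_of_max(phase[k - 1], k) for k in range(1, K + 1)])
    total_var = float(np.var(y))  # population variance of the pooled sample
    with np.errstate(invalid="ignore", divide="ignore"):
        var_frac = np.where(total_var > 0, (amp**2 / 2.0) / total_var, 0.0)
    dof = max(n - p, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    sig = resid_sd if sigma is None else float(sigma)
    red_chisq = (
        float(np.sum((resid / sig) ** 2) / dof) if sig > 0 else 0.0
    )
    return HarmonicFit(
        mean=float(beta[0]),
        cos_coef=a,
        sin_coef=b,
        amplitude=amp,
        phase=phase,
        date_of_max=dates,
        var_fraction=var_frac,
        total_var_captured=float(var_frac.sum()),
        resid_sd=resid_sd,
        red_chisq=red_chisq,
        n_obs=n,
        K=K,
    )


def variance_fractions(fit: HarmonicFit, clim: ClimatologySeries | None = None,
                       relative_to: str = "sample") -> dict:
    """Per-harmonic variance fractions and the dominant harmonic.

    ``relative_to='sample'`` divides each harmonic's variance C_k^2/2 by
    the total sample variance; ``'fitted'`` divides by the summed
    variance of the fitted harmonics only.  Dominant-harmonic selection
    uses the C_k^2 ratio and is invariant to this choice.
    """
    harm_var = fit.amplitude**2 / 2.0
    if relative_to == "fitted":
        tot = harm_var.sum()
        frac = harm_var / tot if tot > 0 else np.zeros_like(harm_var)
    elif relative_to == "sample":
        frac = fit.var_fraction
    else:
        raise ValueError("relative_to must be 'sample' or 'fitted'")
    return {
        "fractions": frac,
        "total": float(np.sum(frac)),
        "dominant_harmonic": fit.dominant_harmonic,
    }


# ---------------------------------------------------------------------------
# composite extrema

_FLAT_TOL = 1e-12


def composite_extrema(fit: HarmonicFit, grid_step: float = 0.01,
                      tie_tol: float = 1e-9) -> CompositeSummary:
    """Extrema of the composite curve via zero-points of its derivative.

    The derivative is scanned on a grid of ``grid_step`` days over
    (0, 365]; each sign change is refined by bisection to |dt| < 1e-8 d.
    Among all stationary points the global maximum and minimum are
    selected; equal extrema (within ``tie_tol`` of the extreme value)
    report the earliest date and set a multiplicity flag.  A flat curve
    (all amplitudes zero) has undefined dates and amplitude 0.
    """
    scale = max(float(np.max(fit.amplitude, initial=0.0)), abs(fit.mean), 1.0)
    if np.all(fit.amplitude <= _FLAT_TOL * scale):
        return CompositeSummary(
            date_of_max=np.nan, date_of_min=np.nan,
            value_at_max=fit.mean, value_at_min=fit.mean,
            composite_amplitude=0.0, degenerate=True,
        )
    grid = np.arange(0.0, YEAR_DAYS + grid_step, grid_step)
    grid[-1] = YEAR_DAYS
    d = fit.derivative(grid)
    roots: list[float] = []
    sign = np.sign(d)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(brentq(fit.derivative, grid[i], grid[i + 1], xtol=1e-8))
    roots.extend(grid[np.flatnonzero(sign == 0)].tolist())
    if not roots:  # cannot happen for a periodic non-flat curve
        raise RuntimeError("no stationary points found")
    roots_arr = np.sort(np.mod(np.asarray(roots), YEAR_DAYS))
    roots_arr[roots_arr == 0.0] = YEAR_DAYS
    roots_arr = np.unique(roots_arr)
    vals = fit.predict(roots_arr)
    vmax, vmin = float(vals.max()), float(vals.min())
    at_max = roots_arr[vals >= vmax - tie_tol * max(scale, 1.0)]
    at_min = roots_arr[vals <= vmin + tie_tol * max(scale, 1.0)]
    return CompositeSummary(
        date_of_max=float(at_max.min()),
        date_of_min=float(at_min.min()),
        value_at_max=vmax,
        value_at_min=vmin,
        composite_amplitude=(vmax - vmin) / 2.0,
        multiple_maxima=len(at_max) > 1,
        multiple_minima=len(at_min) > 1,
    )


# ---------------------------------------------------------------------------
# bootstrap

def _element_period(name: str) -> float:
    if name == "date_of_max_2":
        return YEAR_DAYS / 2.0
    return YEAR_DAYS


def _unwrap(values: np.ndarray, center: float, period: float) -> np.ndarray:
    """Unwrap circular quantities into (center - period/2, center + period/2]."""
    return center + np.mod(values - center + period / 2.0, period) - period / 2.0


def _all_elements(fit: HarmonicFit, comp: CompositeSummary | None) -> dict[str, float]:
    d = fit.elements()
    if comp is not None:
        d.update(comp.elements())
    return d


def bootstrap_fit(clim: ClimatologySeries, n_boot: int = 1000, level: float = 0.95,
                  seed: int | None = None, K: int = 2,
                  include_composite: bool = True) -> BootstrapCI:
    """Case-resampling bootstrap CIs for all harmonic and composite elements.

    Observations are resampled with replacement (case resampling is
    robust to the seasonal heteroscedasticity typical of these data),
    the model is refitted, and percentile intervals are formed.  Date
    elements are circular: replicate dates are unwrapped around the
    point estimate before taking percentiles.
    """
    n = len(clim)
    if n < 20:
        raise ValueError(f"bootstrap requires >= 20 observations, got {n}")
    rng = np.random.default_rng(seed)
    fit0 = fit_harmonics(clim, K=K)
    comp0 = composite_extrema(fit0) if include_composite else None
    point = _all_elements(fit0, comp0)
    reps: dict[str, list[float]] = {k: [] for k in point}
    t, y = clim.day_of_year, clim.values
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bclim = ClimatologySeries(day_of_year=t[idx], values=y[idx])
        bfit = fit_harmonics(bclim, K=K)
        bcomp = composite_extrema(bfit) if include_composite else None
        for key, val in _all_elements(bfit, bcomp).items():
            reps[key].append(val)
    alpha = (1.0 - level) / 2.0
    intervals: dict[str, tuple[float, float]] = {}
    samples: dict[str, np.ndarray] = {}
    for key, vals in reps.items():
        arr = np.asarray(vals, dtype=float)
        if key.startswith("date") and np.isfinite(point[key]):
            arr = _unwrap(arr, point[key], _element_period(key))
        samples[key] = arr
        finite = arr[np.isfinite(arr)]
        if len(finite) == 0:
            intervals[key] = (np.nan, np.nan)
        else:
            intervals[key] = (
                float(np.quantile(finite, alpha)),
                float(np.quantile(finite, 1.0 - alpha)),
            )
    return BootstrapCI(
        intervals=intervals, point=point, n_boot=n_boot, level=level,
        seed=seed, samples=samples,
    )


# ---------------------------------------------------------------------------
# goodness of fit and anomalies

def reduced_chi_squared(fit: HarmonicFit, clim: ClimatologySeries,
                        sigma: float | None = None) -> float:
    """Reduced chi-squared: sum((y - y^m)/sigma)^2 / (n - 2K - 1).

    ``sigma`` defaults to the fit's residual SD, which yields a value
    of ~1 by construction; pass a measurement-error SD for a genuine
    goodness-of-fit check.
    """
    resid = clim.values - fit.predict(clim.day_of_year)
    sig = fit.resid_sd if sigma is None else float(sigma)
    if sig <= 0:
        return 0.0 if np.allclose(resid, 0.0) else np.inf
    dof = max(fit.n_obs - (2 * fit.K + 1), 1)
    return float(np.sum((resid / sig) ** 2) / dof)


def deseasonalize(series: SampleSeries, fit: HarmonicFit) -> SampleSeries:
    """Observation minus fitted climatological value at its day of year."""
    doy = day_of_year_365(series.times)
    anomalies = series.values - fit.predict(doy)
    return SampleSeries(
        site=series.site,
        variable=f"{series.variable}_anomaly" if series.variable else "anomaly",
        times=series.times,
        values=anomalies,
        flags=series.flags.copy(),
        units=series.units,
        truth=series.truth,
    )


def circular_delta(late: float, early: float, period: float = YEAR_DAYS) -> float:
    """Signed circular difference late - early, in (-period/2, period/2]."""
    d = (late - early) % period
    if d > period / 2.0:
        d -= period
    return d
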