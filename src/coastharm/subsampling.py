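"""Simulated low-frequency sampling experiments.

Two observing-system experiments score sparse manual-style sampling
against a dense (daily-averaged sonde) reference:

1. *Density-matched subsampling* — each of ``n_trials`` trials draws,
   uniformly without replacement within each calendar quarter of the
   record, the same number of days a manual programme would have
   visited, refits the harmonic model, and scores the trial curve
   against the reference curve with RMSE, nRMSE (RMSE over the SD of
   the deseasonalized anomalies of the reference record) and the
   Nash-Sutcliffe efficiency NSE = 1 - (RMSE / sigma_trial)^2, where
   sigma_trial is the SD of the trial's sampled values.  NSE >= 0.90
   is classed very good, 0.80-0.90 good, 0.65-0.80 acceptable and
   < 0.65 unsatisfactory.

2. *Duration sweep* — for each candidate duration N years of quarterly
   sampling, trials draw N days per season from the record's pooled
   day-of-year distribution (so durations beyond the reference record
   length are still well defined), and the trial-to-trial mean and SD
   of every harmonic element are tracked as a function of N.  SDs are
   normalized (nSD) by their large-N asymptote, and the minimum
   adequate duration is the smallest N whose trial-mean element lies
   inside the reference bootstrap CI at two successive grid values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonics import (
    BootstrapCI,
    CompositeSummary,
    HarmonicFit,
    bootstrap_fit,
    composite_extrema,
    deseasonalize,
    fit_harmonics,
    to_climatology,
    _element_period,
    _unwrap,
)
from .series import SampleSeries

YEAR_GRID = np.arange(1.0, 366.0)  # integer year-days for curve comparison
DEFAULT_N_GRID = (5, 10, 15, 20, 25, 30, 40, 50)

NSE_CLASSES = (
    (0.90, "very good"),
    (0.80, "good"),
    (0.65, "acceptable"),
)


def nse_class(value: float) -> str:
    """Qualitative skill class of a Nash-Sutcliffe efficiency value."""
    for threshold, label in NSE_CLASSES:
        if value >= threshold:
            return label
    return "unsatisfactory"


@dataclass
class ReferenceFit:
    """The dense-record truth surface all trials are scored against."""

    fit: HarmonicFit
    composite: CompositeSummary
    ci: BootstrapCI
    anomaly_sd: float
    curve: np.ndarray          # fitted values on integer year-days 1..365
    degenerate_sd: bool = False  # anomaly_sd == 0: nRMSE undefined


@dataclass
class SubsampleTrial:
    times: pd.DatetimeIndex
    values: np.ndarray
    fit: HarmonicFit
    composite: CompositeSummary
    rmse: float
    nrmse: float
    nse: float
    nse_label: str


@dataclass
class DurationCurve:
    """Per-duration statistics of the duration-sweep experiment."""

    n_yrs: np.ndarray                       # strictly increasing grid
    element_mean: dict[str, np.ndarray]     # per element, per N
    element_sd: dict[str, np.ndarray]
    nsd: dict[str, np.ndarray] = field(default_factory=dict)
    mean_nrmse: np.ndarray | None = None
    n_trials: int = 200
    variable: str = ""


@dataclass
class MinDurationResult:
    element: str
    n_min: float
    attained: bool
    note: str = ""


# ---------------------------------------------------------------------------
# reference

def reference_fit(daily_series: SampleSeries, n_boot: int = 1000,
                  seed: int | None = None, K: int = 2) -> ReferenceFit:
    """Fit the dense reference record: harmonic fit, composite extrema,
    bootstrap CIs and the SD of its deseasonalized anomalies."""
    if daily_series.span_years < 2.0:
        raise ValueError("reference record must span >= 2 years")
    clim = to_climatology(daily_series)
    fit = fit_harmonics(clim, K=K)
    comp = composite_extrema(fit)
    ci = bootstrap_fit(clim, n_boot=n_boot, seed=seed, K=K)
    anomalies = deseasonalize(daily_series, fit)
    anomaly_sd = float(np.std(anomalies.values, ddof=1))
    # numerically zero anomalies (noise-free input) leave nRMSE undefined
    degenerate = anomaly_sd <= 1e-12 * max(1.0, float(np.std(daily_series.values)))
    if degenerate:
        anomaly_sd = 0.0
    return ReferenceFit(
        fit=fit, composite=comp, ci=ci, anomaly_sd=anomaly_sd,
        curve=fit.predict(YEAR_GRID),
        degenerate_sd=degenerate,
    )


# ---------------------------------------------------------------------------
# skill scores

def rmse_fit(reference_curve: np.ndarray, trial_curve: np.ndarray,
             nu: int) -> float:
    """RMSE between two fitted curves on integer year-days.

    ``nu`` is the number of subsampled values in the trial, used as the
    degrees-of-freedom estimate, so sparse trials are penalized even
    when their smooth curves happen to lie close to the reference.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    diff = np.asarray(reference_curve) - np.asarray(trial_curve)
    return float(np.sqrt(np.sum(diff**2) / nu))


def nrmse(rmse: float, anomaly_sd: float) -> float:
    """RMSE normalized by the reference record's anomaly SD."""
    if not anomaly_sd > 0:
        return np.nan  # undefined for a noise-free reference
    return rmse / anomaly_sd


def nse(rmse: float, trial_values: np.ndarray) -> tuple[float, str]:
    """Nash-Sutcliffe efficiency 1 - (RMSE/sigma_trial)^2 with skill class."""
    sigma = float(np.std(np.asarray(trial_values), ddof=1))
    if not sigma > 0:
        return np.nan, "undefined"
    value = 1.0 - (rmse / sigma) ** 2
    return value, nse_class(value)


# ---------------------------------------------------------------------------
# experiment 1: density-matched subsampling

def _quarters(times: pd.DatetimeIndex) -> np.ndarray:
    return ((times.month.to_numpy() - 1) // 3) + 1


def subsample_density(daily_series: SampleSeries, counts_per_quarter,
                      reference: ReferenceFit | None = None,
                      n_trials: int = 200, seed: int | None = None,
                      K: int = 2) -> list[SubsampleTrial]:
    """Density-matched subsampling trials of a dense daily record.

    ``counts_per_quarter`` is either one int (same count for all four
    quarters) or a length-4 sequence; each trial draws that many days
    uniformly without replacement from the pooled days of each calendar
    quarter, refits the harmonic model and scores it.
    """
    if reference is None:
        reference = reference_fit(daily_series, seed=seed)
    if np.isscalar(counts_per_quarter):
        counts = {q: int(counts_per_quarter) for q in range(1, 5)}
    else:
        counts = {q: int(c) for q, c in zip(range(1, 5), counts_per_quarter)}
    rng = np.random.default_rng(seed)
    quarters = _quarters(daily_series.times)
    pools = {q: np.flatnonzero(quarters == q) for q in range(1, 5)}
    for q, c in counts.items():
        if c > len(pools[q]):
            raise ValueError(
                f"requested {c} samples from quarter {q} with only "
                f"{len(pools[q])} available days"
            )
    trials = []
    for _ in range(n_trials):
        idx = np.sort(np.concatenate([
            rng.choice(pools[q], size=counts[q], replace=False)
            for q in range(1, 5)
        ]))
        sub = daily_series.select(np.isin(np.arange(len(daily_series)), idx))
        fit = fit_harmonics(to_climatology(sub), K=K)
        comp = composite_extrema(fit)
        r = rmse_fit(reference.curve, fit.predict(YEAR_GRID), nu=len(sub))
        n = nrmse(r, reference.anomaly_sd)
        e, label = nse(r, sub.values)
        trials.append(SubsampleTrial(
            times=sub.times, values=sub.values, fit=fit, composite=comp,
            rmse=r, nrmse=n, nse=e, nse_label=label,
        ))
    return trials


def trial_summary(trials: list[SubsampleTrial]) -> dict[str, float]:
    """Mean and SD of the skill scores over a set of trials."""
    r = np.array([t.rmse for t in trials])
    n = np.array([t.nrmse for t in trials])
    e = np.array([t.nse for t in trials])
    mean_nse = float(np.nanmean(e))
    return {
        "mean_rmse": float(r.mean()), "sd_rmse": float(r.std(ddof=1)),
        "mean_nrmse": float(np.nanmean(n)), "sd_nrmse": float(np.nanstd(n, ddof=1)),
        "mean_nse": mean_nse, "sd_nse": float(np.nanstd(e, ddof=1)),
        "nse_class": nse_class(mean_nse),
        "n_trials": len(trials),
    }


# ---------------------------------------------------------------------------
# experiment 2: duration sweep

def _trial_elements(fit: HarmonicFit, comp: CompositeSummary) -> dict[str, float]:
    d = fit.elements()
    d.update(comp.elements())
    return d


def sweep_duration(daily_series: SampleSeries,
                   n_yrs_grid=DEFAULT_N_GRID,
                   reference: ReferenceFit | None = None,
                   n_trials: int = 200, seed: int | None = None,
                   K: int = 2) -> DurationCurve:
    """Duration sweep: N quarterly samples per season for each N in the grid.

    Each trial draws N days without replacement from the pooled
    day-of-year record of each calendar quarter (4N samples per trial),
    so N may exceed the number of years the dense record actually
    spans.  Element means/SDs per N use circular unwrapping around the
    reference point estimate for date elements.
    """
    grid = np.asarray(sorted(n_yrs_grid), dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("n_yrs_grid must be strictly increasing")
    if reference is None:
        reference = reference_fit(daily_series, seed=seed)
    rng = np.random.default_rng(seed)
    quarters = _quarters(daily_series.times)
    pools = {q: np.flatnonzero(quarters == q) for q in range(1, 5)}
    smallest_pool = min(len(p) for p in pools.values())
    if grid[-1] > smallest_pool:
        raise ValueError(
            f"largest N ({grid[-1]:.0f}) exceeds the {smallest_pool} pooled "
            "days available in the sparsest quarter"
        )
    elements = list(_trial_elements(reference.fit, reference.composite))
    means = {k: np.empty(len(grid)) for k in elements}
    sds = {k: np.empty(len(grid)) for k in elements}
    mean_nrmse = np.empty(len(grid))
    for gi, n_yrs in enumerate(grid):
        per_trial = {k: np.empty(n_trials) for k in elements}
        nr = np.empty(n_trials)
        for ti in range(n_trials):
            idx = np.concatenate([
                rng.choice(pools[q], size=int(n_yrs), replace=False)
                for q in range(1, 5)
            ])
            sub = daily_series.select(np.isin(np.arange(len(daily_series)), idx))
            fit = fit_harmonics(to_climatology(sub), K=K)
            comp = composite_extrema(fit)
            for k, v in _trial_elements(fit, comp).items():
                per_trial[k][ti] = v
            nr[ti] = nrmse(
                rmse_fit(reference.curve, fit.predict(YEAR_GRID), nu=len(sub)),
                reference.anomaly_sd,
            )
        for k in elements:
            vals = per_trial[k]
            if k.startswith("date") and np.isfinite(reference.ci.point[k]):
                vals = _unwrap(vals, reference.ci.point[k], _element_period(k))
            means[k][gi] = np.nanmean(vals)
            sds[k][gi] = np.nanstd(vals, ddof=1)
        mean_nrmse[gi] = np.nanmean(nr)
    curve = DurationCurve(
        n_yrs=grid, element_mean=means, element_sd=sds,
        mean_nrmse=mean_nrmse, n_trials=n_trials,
        variable=daily_series.variable,
    )
    for k in elements:
        curve.nsd[k] = nsd(curve, k)
    return curve


def nsd(curve: DurationCurve, element: str) -> np.ndarray:
    """Trial-to-trial SD of an element normalized by its large-N asymptote.

    The asymptote is the mean SD over the upper half of the N grid,
    where the SD has effectively plateaued, so nSD ~ 1 at large N and
    > 1 where the duration is too short to pin the element down.
    """
    sd = curve.element_sd[element]
    upper = sd[len(sd) // 2:]
    asymptote = float(np.mean(upper))
    if not asymptote > 0:
        return np.full_like(sd, np.nan)
    return sd / asymptote


def minimum_duration(curve: DurationCurve, reference_ci: BootstrapCI,
                     elements: list[str] | None = None) -> list[MinDurationResult]:
    """Minimum adequate sampling duration per composite harmonic element.

    N_min is the smallest grid N at which the trial-mean element falls
    inside the reference bootstrap CI at that N *and* at the next grid
    value.  When no N satisfies the rule, the N whose trial mean is
    closest to the CI midpoint is returned with ``attained=False`` and
    a note, so the variable can be reported as not converged.
    """
    if elements is None:
        elements = [k for k in curve.element_mean
                    if k in reference_ci.intervals]
    results = []
    for el in elements:
        means = curve.element_mean[el]
        inside = np.array([reference_ci.contains(el, m) for m in means])
        n_min, attained, note = np.nan, False, ""
        for i in range(len(inside) - 1):
            if inside[i] and inside[i + 1]:
                n_min, attained = float(curve.n_yrs[i]), True
                break
        if not attained:
            lo, hi = reference_ci.intervals[el]
            mid = (lo + hi) / 2.0
            vals = means
            if el.startswith("date"):
                vals = _unwrap(means, reference_ci.point[el], _element_period(el))
            i = int(np.nanargmin(np.abs(vals - mid)))
            n_min = float(curve.n_yrs[i])
            note = "CI never bracketed at two sequential N; closest value selected"
        results.append(MinDurationResult(element=el, n_min=n_min,
                                         attained=attained, note=note))
    return results


def duration_table(curve: DurationCurve) -> pd.DataFrame:
    """Tidy (variable, N_yrs, element, mean, sd, nsd, nrmse) table."""
    rows = []
    for gi, n in enumerate(curve.n_yrs):
        for el in curve.element_mean:
            rows.append({
                "variable": curve.variable,
                "n_yrs": n,
                "element": el,
                "mean": curve.element_mean[el][gi],
                "sd": curve.element_sd[el][gi],
                "nsd": curve.nsd[el][gi] if el in curve.nsd else np.nan,
                "mean_nrmse": curve.mean_nrmse[gi],
            })
    return pd.DataFrame(rows)
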