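"""Screening and transformation steps applied before analysis.

Four operations: a sequential spike filter (a point is dropped when it
jumps more than one within-year standard deviation away from the
preceding retained point), a single-pass Chauvenet outlier screen,
base-10 log transform of chlorophyll, and daily averaging of
sub-daily records.  QC only changes membership, never values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .series import SampleSeries

FLAG_SPIKE = "S"
FLAG_CHAUVENET = "C"
FLAG_NONPOSITIVE = "N"


@dataclass
class QCReport:
    n_in: int
    n_flagged_spike: int = 0
    n_flagged_chauvenet: int = 0
    n_flagged_nonpositive: int = 0
    n_out: int = 0
    flags: np.ndarray | None = field(default=None, repr=False)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_flagged_spike": self.n_flagged_spike,
            "n_flagged_chauvenet": self.n_flagged_chauvenet,
            "n_flagged_nonpositive": self.n_flagged_nonpositive,
            "n_out": self.n_out,
            "warnings": list(self.warnings),
        }


def yearly_sd(series: SampleSeries) -> dict[int, float]:
    """Sample SD of raw values per calendar year."""
    years = series.times.year
    df = pd.DataFrame({"year": years, "value": series.values})
    return df.groupby("year")["value"].std(ddof=1).fillna(0.0).to_dict()


def spike_filter(series: SampleSeries,
                 yearly_sd_map: dict[int, float] | None = None,
                 n_sd: float = 1.0) -> tuple[SampleSeries, QCReport]:
    """Drop points that jump more than ``n_sd`` yearly SDs from the
    preceding retained point.

    The yearly SD is derived from the raw (unfiltered) values of the
    point's own calendar year; the comparison is always against the
    most recent *kept* point, so a spike does not poison the baseline
    for the points after it.  The first point is always kept.
    """
    n = len(series)
    if n < 2:
        rep = QCReport(n_in=n, n_out=n,
                       flags=np.full(n, "", dtype=object),
                       warnings=["series has < 2 points; spike filter skipped"])
        return series, rep
    if yearly_sd_map is None:
        yearly_sd_map = yearly_sd(series)
    years = series.times.year.to_numpy()
    values = series.values
    keep = np.ones(n, dtype=bool)
    last_kept = values[0]
    for i in range(1, n):
        sd = yearly_sd_map.get(int(years[i]), 0.0)
        if abs(values[i] - last_kept) > n_sd * sd:
            keep[i] = False
        else:
            last_kept = values[i]
    flags = np.where(keep, "", FLAG_SPIKE).astype(object)
    out = series.select(keep)
    rep = QCReport(
        n_in=n,
        n_flagged_spike=int((~keep).sum()),
        n_out=int(keep.sum()),
        flags=flags,
    )
    return out, rep


def chauvenet_mask(values: np.ndarray, iterate: bool = False) -> np.ndarray:
    """Boolean mask of points rejected by Chauvenet's criterion.

    A point is rejected when n * P(|Z| > |z_i|) < 0.5 under a normal
    model with the sample mean and SD.  Default is a single pass;
    ``iterate=True`` repeats on the retained points until no further
    rejection.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    rejected = np.zeros(n, dtype=bool)
    if n < 4:
        return rejected
    while True:
        kept = values[~rejected]
        m, sd = kept.mean(), kept.std(ddof=1)
        if sd == 0:
            return rejected
        z = np.abs(values - m) / sd
        # P(|Z| > z) = erfc(z / sqrt 2)
        new = (~rejected) & (len(kept) * erfc(z / np.sqrt(2.0)) < 0.5)
        if not new.any():
            return rejected
        rejected |= new
        if not iterate:
            return rejected


def chauvenet_screen(series: SampleSeries,
                     iterate: bool = False) -> tuple[SampleSeries, QCReport]:
    """Apply Chauvenet's criterion over the whole record of one variable."""
    n = len(series)
    warnings_: list[str] = []
    if n < 4:
        warnings_.append("fewer than 4 points; Chauvenet screen skipped")
        mask = np.zeros(n, dtype=bool)
    else:
        mask = chauvenet_mask(series.values, iterate=iterate)
    flags = np.where(mask, FLAG_CHAUVENET, "").astype(object)
    out = series.select(~mask)
    rep = QCReport(
        n_in=n,
        n_flagged_chauvenet=int(mask.sum()),
        n_out=int((~mask).sum()),
        flags=flags,
        warnings=warnings_,
    )
    return out, rep


def log10_chl(series: SampleSeries) -> tuple[SampleSeries, QCReport]:
    """Base-10 log transform of chlorophyll; nonpositive values dropped."""
    ok = series.values > 0
    out = series.select(ok)
    out = out.replace(
        variable="log10chl",
        values=np.log10(out.values),
        units="log10(ug/L)",
    )
    rep = QCReport(
        n_in=len(series),
        n_flagged_nonpositive=int((~ok).sum()),
        n_out=int(ok.sum()),
        flags=np.where(ok, "", FLAG_NONPOSITIVE).astype(object),
    )
    return out, rep


def daily_average(series: SampleSeries,
                  min_samples: int = 1) -> tuple[SampleSeries, pd.Series]:
    """Average sub-daily samples to one value per calendar day.

    Days with no retained samples are absent (not zero-filled); the
    per-day sample count is returned so users can filter sparse days.
    Daily averaging removes the diurnal cycle from sonde records.
    """
    dates = series.times.normalize()
    df = pd.DataFrame({"date": dates, "value": series.values})
    g = df.groupby("date")["value"]
    means = g.mean()
    counts = g.count()
    ok = counts >= min_samples
    means, counts = means[ok], counts[ok]
    daily = SampleSeries(
        site=series.site,
        variable=series.variable,
        times=pd.DatetimeIndex(means.index) + pd.Timedelta(hours=12),
        values=means.to_numpy(),
        units=series.units,
        truth=series.truth,
    )
    return daily, counts
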