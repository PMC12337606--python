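"""Timestamped water-quality sample series and its on-disk CSV form.

A :class:`SampleSeries` is the universal currency of the pipeline: one
variable at one site, strictly time-sorted, with a per-sample QC flag
column.  Canonical units are fixed per variable (temperature in deg C,
salinity in psu, dissolved oxygen and AOU in mg/L, chlorophyll-a in
ug/L, log10-chlorophyll in log10(ug/L)).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical variable names -> units
VARIABLE_UNITS = {
    "temperature": "degC",
    "salinity": "psu",
    "do": "mg/L",
    "chl": "ug/L",
    "log10chl": "log10(ug/L)",
    "aou": "mg/L",
    "anomaly": "",
}

REQUIRED_COLUMNS = ("site", "variable", "timestamp", "value")


class SeriesError(ValueError):
    """Raised for malformed or inconsistent series input."""


@dataclass
class SampleSeries:
    """One variable at one site: timestamps, values, QC flags.

    Timestamps are held as a pandas DatetimeIndex and kept strictly
    increasing; duplicate timestamps are permitted only transiently
    (the reader warns and keeps first occurrence).
    """

    site: str
    variable: str
    times: pd.DatetimeIndex
    values: np.ndarray
    flags: np.ndarray | None = None
    units: str = ""
    warnings_: list[str] = field(default_factory=list)
    #: ground-truth sidecar for synthetic series (None for real data)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.values), "", dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if len(self.times) != len(self.values):
            raise SeriesError("times and values length mismatch")
        if len(self.flags) != len(self.values):
            raise SeriesError("flags length mismatch")
        if not self.units and self.variable in VARIABLE_UNITS:
            self.units = VARIABLE_UNITS[self.variable]
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            order = np.argsort(self.times.values, kind="stable")
            self.times = self.times[order]
            self.values = self.values[order]
            self.flags = self.flags[order]
            self.warnings_.append("input timestamps were out of order; sorted")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def span_years(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return (self.times[-1] - self.times[0]) / pd.Timedelta(days=365.25)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site,
                "variable": self.variable,
                "timestamp": self.times,
                "value": self.values,
                "flag": self.flags,
            }
        )

    def replace(self, **kwargs) -> "SampleSeries":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def select(self, mask: np.ndarray) -> "SampleSeries":
        """Return the sub-series where ``mask`` is True (truth carried over)."""
        mask = np.asarray(mask, dtype=bool)
        return SampleSeries(
            site=self.site,
            variable=self.variable,
            times=self.times[mask],
            values=self.values[mask],
            flags=self.flags[mask],
            units=self.units,
            warnings_=list(self.warnings_),
            truth=self.truth,
        )


def read_series(path, schema: dict | None = None) -> SampleSeries:
    """Read a :class:`SampleSeries` from CSV.

    The expected schema is ``site,variable,timestamp,value[,flag]`` with
    an ISO-8601 timestamp column.  Unknown columns are ignored with a
    warning; rows whose timestamp or value fails to parse are dropped
    and counted.  ``schema`` may rename columns, e.g.
    ``{"timestamp": "DateTime"}`` maps the canonical name to the file's.
    """
    colmap = {k: k for k in (*REQUIRED_COLUMNS, "flag")}
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in raw.columns]
    if missing:
        raise SeriesError(
            f"missing required column(s): {', '.join(colmap[c] for c in missing)}"
        )
    known = {colmap[c] for c in (*REQUIRED_COLUMNS, "flag")}
    unknown = [c for c in raw.columns if c not in known]
    warn_msgs: list[str] = []
    if unknown:
        warn_msgs.append(f"ignoring unknown column(s): {', '.join(unknown)}")

    ts = pd.to_datetime(raw[colmap["timestamp"]], errors="coerce", utc=True, format="mixed")
    vals = pd.to_numeric(raw[colmap["value"]], errors="coerce")
    bad = ts.isna() | vals.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        warn_msgs.append(f"rejected {int(bad.sum())} malformed row(s) at line(s) {lines}")
    ok = ~bad
    sites = raw.loc[ok, colmap["site"]].unique()
    variables = raw.loc[ok, colmap["variable"]].unique()
    if len(sites) > 1 or len(variables) > 1:
        raise SeriesError(
            "a SampleSeries holds one (site, variable); found "
            f"sites={list(sites)} variables={list(variables)}"
        )
    flags = (
        raw.loc[ok, colmap["flag"]].fillna("").to_numpy(dtype=object)
        if colmap["flag"] in raw.columns
        else None
    )
    for m in warn_msgs:
        warnings.warn(m, stacklevel=2)
    return SampleSeries(
        site=str(sites[0]) if len(sites) else "",
        variable=str(variables[0]) if len(variables) else "",
        times=pd.DatetimeIndex(ts[ok]),
        values=vals[ok].to_numpy(dtype=float),
        flags=flags,
        warnings_=warn_msgs,
    )


def write_series(series: SampleSeries, path) -> None:
    """Write a series to CSV in the canonical schema (ISO-8601 timestamps)."""
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df.to_csv(path, index=False)
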