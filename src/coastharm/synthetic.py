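"""Synthetic sonde-like and manual-sample-like water-quality series.

Every downstream stage of the pipeline is tested against series with
known ground truth.  A series is the sum of

* an annual + semi-annual seasonal cycle (amplitudes ``amp1``/``amp2``
  peaking at year-days ``dmax1``/``dmax2``),
* a linear trend in units per year,
* an optional diurnal cycle (sonde mode),
* AR(1) noise generated on the sampling grid (``ar1_rho`` is per step:
  a per-step rho r for 15-min data corresponds to a per-day rho of
  r**96), and
* sparse spikes of +/- ``spike_scale`` * ``noise_sd`` at uniformly
  random times, recorded in the ground-truth sidecar so QC tests can
  compute confusion counts.

Gap windows are removed after generation.  Two cadence families are
supported: sub-daily/daily grids via any pandas frequency alias
("15min", "h", "D", ...) emulating automated sondes, and the literal
cadence "quarterly" emulating manual sampling at a fixed local
time-of-day once per quarter, the field protocol for multi-decade
monitoring programmes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .harmonics import YEAR_DAYS, day_of_year_365
from .oxygen import o2_saturation
from .series import SampleSeries

DAYS_PER_YEAR = 365.25  # calendar years for the trend clock


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of one synthetic series."""

    mean: float
    amp1: float = 0.0
    amp2: float = 0.0
    dmax1: float = 200.0
    dmax2: float = 100.0
    trend: float = 0.0            # units per year
    ar1_rho: float = 0.0          # per sampling step
    noise_sd: float = 0.0         # innovation SD
    diurnal_amp: float = 0.0
    diurnal_peak_hour: float = 15.0
    cadence: str = "D"            # pandas freq alias, or "quarterly"
    start: str = "2010-01-01"
    end: str = "2019-12-31"
    sample_hour: float = 10.0     # local time-of-day for quarterly sampling
    quarterly_day: int = 45       # day within each quarter for quarterly sampling
    gap_spec: list[tuple[str, str]] = field(default_factory=list)
    spike_rate: float = 0.0       # fraction of points spiked
    spike_scale: float = 6.0      # in units of noise_sd
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amp1 < 0 or self.amp2 < 0 or self.diurnal_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        for d in (self.dmax1, self.dmax2):
            if not 1 <= d <= YEAR_DAYS:
                raise ValueError(f"dmax must be in [1, 365], got {d}")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.spike_rate < 0.1:
            raise ValueError("spike_rate must be in [0, 0.1)")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("end must be after start")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _time_grid(cfg: SyntheticConfig) -> pd.DatetimeIndex:
    start, end = pd.Timestamp(cfg.start), pd.Timestamp(cfg.end)
    if cfg.cadence == "quarterly":
        quarters = pd.date_range(start.normalize(), end, freq="QS")
        times = quarters + pd.Timedelta(days=cfg.quarterly_day,
                                        hours=cfg.sample_hour)
        return pd.DatetimeIndex([t for t in times if start <= t <= end])
    return pd.date_range(start, end, freq=cfg.cadence)


def seasonal_signal(doy: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free seasonal component at climatological day-of-year."""
    w = 2.0 * np.pi / YEAR_DAYS
    return (cfg.amp1 * np.cos(w * (doy - cfg.dmax1))
            + cfg.amp2 * np.cos(2.0 * w * (doy - cfg.dmax2)))


def _ar1_noise(n: int, rho: float, innovation_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if innovation_sd == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, innovation_sd, size=n)
    if rho == 0.0:
        return eps
    x = lfilter([1.0], [1.0, -rho], eps)
    # stationary start: add the decaying contribution of x_{-1}
    x0 = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - rho**2))
    return x + x0 * rho ** np.arange(1, n + 1)


def generate_series(cfg: SyntheticConfig, site: str = "SYN",
                    variable: str = "temperature") -> SampleSeries:
    """Generate one series from its ground-truth configuration.

    The returned series carries a ``truth`` dict (full config, spike
    times, noise-free component) for parameter-recovery testing;
    identical seeds give bitwise-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    times = _time_grid(cfg)
    if len(times) == 0:
        raise ValueError("date range and cadence produce no samples")
    doy = day_of_year_365(times)
    t_years = (times - times[0]) / pd.Timedelta(days=DAYS_PER_YEAR)
    signal = cfg.mean + seasonal_signal(doy, cfg) + cfg.trend * np.asarray(t_years)
    if cfg.diurnal_amp > 0:
        hour = times.hour + times.minute / 60.0 + times.second / 3600.0
        signal = signal + cfg.diurnal_amp * np.cos(
            2.0 * np.pi * (np.asarray(hour) - cfg.diurnal_peak_hour) / 24.0
        )
    noise = _ar1_noise(len(times), cfg.ar1_rho, cfg.noise_sd, rng)
    values = signal + noise

    n_spikes = int(round(cfg.spike_rate * len(times)))
    spike_idx = np.array([], dtype=int)
    if n_spikes > 0:
        spike_idx = np.sort(rng.choice(len(times), size=n_spikes, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        values[spike_idx] += signs * cfg.spike_scale * cfg.noise_sd

    flags = np.full(len(times), "", dtype=object)
    warnings_: list[str] = []
    span_days = (times[-1] - times[0]) / pd.Timedelta(days=1)
    if span_days < YEAR_DAYS:
        warnings_.append(
            "series spans less than one full year; climatological fits "
            "will be poorly constrained"
        )

    keep = np.ones(len(times), dtype=bool)
    for g0, g1 in cfg.gap_spec:
        keep &= ~((times >= pd.Timestamp(g0)) & (times <= pd.Timestamp(g1)))

    truth = {
        "config": cfg.to_dict(),
        "spike_times": [times[i].isoformat() for i in spike_idx if keep[i]],
        "n_spikes_injected": int(n_spikes),
        "n_spikes_surviving_gaps": int(keep[spike_idx].sum()) if n_spikes else 0,
    }
    return SampleSeries(
        site=site,
        variable=variable,
        times=times[keep],
        values=values[keep],
        flags=flags[keep],
        warnings_=warnings_,
        truth=truth,
    )


def default_suite_configs(cadence: str = "D", start: str = "2010-01-01",
                          end: str = "2019-12-31",
                          noise: bool = True) -> dict[str, SyntheticConfig]:
    """Configurations emulating a shallow mainland coastal-lagoon site.

    Scales follow multi-decade observations at mid-Atlantic lagoon
    sites: temperature with an ~11.8 degC seasonal amplitude peaking
    near year-day 214 and a weak warming trend; salinity with mixed
    annual/semi-annual harmonics of order 1 psu; an AOU cycle of
    ~0.8 mg/L amplitude peaking in late summer (year-day ~241); and
    log10-chlorophyll with a 0.3 log10(ug/L) annual amplitude.  The
    ``chl`` config is specified on the log10 scale; the ``aou`` config
    defines the oxygen-deficit signal subtracted from saturation when
    dissolved oxygen is generated.
    """
    f = 1.0 if noise else 0.0
    common = dict(cadence=cadence, start=start, end=end)
    return {
        "temperature": SyntheticConfig(
            mean=17.0, amp1=11.8, amp2=0.6, dmax1=214, dmax2=30,
            trend=0.07, ar1_rho=0.6, noise_sd=f * 1.2, **common),
        "salinity": SyntheticConfig(
            mean=31.0, amp1=0.9, amp2=0.7, dmax1=227, dmax2=120,
            trend=0.0, ar1_rho=0.6, noise_sd=f * 0.8, **common),
        "chl": SyntheticConfig(  # log10(ug/L) scale
            mean=0.6, amp1=0.30, amp2=0.12, dmax1=215, dmax2=150,
            trend=0.0, ar1_rho=0.5, noise_sd=f * 0.15, **common),
        "aou": SyntheticConfig(
            mean=0.4, amp1=0.8, amp2=0.1, dmax1=241, dmax2=60,
            trend=0.0, ar1_rho=0.5, noise_sd=f * 0.5, **common),
    }


def generate_site_suite(configs: dict[str, SyntheticConfig] | None = None,
                        seed: int | None = None,
                        site: str = "SYN") -> dict[str, SampleSeries]:
    """Generate a coherent multi-variable site: T, S, DO, Chl (+ AOU truth).

    Temperature, salinity and chlorophyll come from their own configs on
    a shared time base.  Dissolved oxygen is constructed as
    ``o2_saturation(T_obs, S_obs) - AOU_signal`` where the AOU config
    supplies the injected oxygen-deficit cycle and DO noise, so the
    oxygen module recovers the injected AOU cycle exactly in the
    noise-free limit.  Chlorophyll is log-normal: its config acts on the
    log10 scale and the emitted series is ``10**x`` in ug/L.

    Returns a dict with keys ``temperature``, ``salinity``, ``do``,
    ``chl`` and ``aou_truth`` (the injected AOU series).
    """
    if configs is None:
        configs = default_suite_configs()
    required = {"temperature", "salinity", "chl", "aou"}
    if not required <= set(configs):
        raise ValueError(f"configs must include {sorted(required)}")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4)]
    cfgs = {k: dataclasses.replace(configs[k], seed=seeds[i] % (2**31))
            for i, k in enumerate(["temperature", "salinity", "chl", "aou"])}

    temp = generate_series(cfgs["temperature"], site=site, variable="temperature")
    sal = generate_series(cfgs["salinity"], site=site, variable="salinity")
    if not temp.times.equals(sal.times):
        raise ValueError("temperature and salinity configs must share a time base")
    # keep T and S inside the physical range of the solubility fit
    temp = temp.replace(values=np.clip(temp.values, -2.0, 40.0))
    sal = sal.replace(values=np.clip(sal.values, 0.0, 42.0))

    aou_sig = generate_series(cfgs["aou"], site=site, variable="aou")
    if not aou_sig.times.equals(temp.times):
        raise ValueError("aou config must share the T/S time base")
    do_values = o2_saturation(temp.values, sal.values) - aou_sig.values
    do = SampleSeries(
        site=site, variable="do", times=temp.times,
        values=do_values, units="mg/L",
        truth={"config": cfgs["aou"].to_dict(), "construction": "o2sat(T,S) - aou"},
    )

    log_chl = generate_series(cfgs["chl"], site=site, variable="log10chl")
    chl = log_chl.replace(variable="chl", values=10.0 ** log_chl.values,
                          units="ug/L")
    return {
        "temperature": temp,
        "salinity": sal,
        "do": do,
        "chl": chl,
        "aou_truth": aou_sig,
    }


def write_truth_sidecar(series: SampleSeries, path) -> None:
    """Write the ground-truth sidecar JSON next to an exported series."""
    if series.truth is None:
        raise ValueError("series has no ground truth attached")
    with open(path, "w") as fh:
        json.dump(series.truth, fh, indent=2, default=str)
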