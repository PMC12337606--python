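# coastharm

Seasonal harmonic analysis, long-term trend detection and
sampling-design (subsampling) experiments for coastal water-quality
time series — temperature, salinity, dissolved oxygen, chlorophyll-a
and apparent oxygen utilization (AOU).

Coastal monitoring programmes face a basic design trade-off: a few
years of high-frequency sonde data (15-minute cadence) versus decades
of low-frequency manual sampling (roughly quarterly). `coastharm`
implements the statistical toolkit for working with both:

* **Climatological harmonic model.** Observations are pooled by day of
  year t (1..365) and fitted by OLS to

      y^m(t) = ȳ + Σ_{k=1,2} [ a_k cos(2πkt/365) + b_k sin(2πkt/365) ]

  where k = 1 is the annual and k = 2 the semi-annual harmonic.  Each
  harmonic is summarised by its amplitude C_k = √(a_k² + b_k²), phase
  φ_k = atan2(b_k, a_k) and date of maximum; the composite curve
  (mean + both harmonics) by the dates/values of its extrema, located
  at the zero-points of dy^m/dt, and by the composite seasonal
  amplitude (max − min)/2.  Per-harmonic variance fractions C_k²/2
  relative to the sample variance identify the dominant harmonic, and
  case-resampling bootstrap gives percentile confidence intervals for
  every element.
* **QC:** sequential spike filter (drop a point farther than one
  within-year SD from the preceding retained point), single-pass
  Chauvenet outlier criterion (reject when n·P(|Z|>|z_i|) < 0.5),
  log10 chlorophyll transform, daily averaging.
* **Oxygen:** Garcia–Gordon (1992) solubility (Benson–Krause
  coefficients) and AOU = O2_sat(T,S) − DO.
* **Trends:** GLS with AR(1) errors on deseasonalized anomalies
  (anomaly = y − y^m(doy)), multi-site trend pooling, and split-half
  analysis of shifting seasonal amplitude and phenology.
* **Subsampling experiments:** score sparse quarterly sampling designs
  against a dense reference via RMSE/nRMSE/Nash–Sutcliffe efficiency,
  sweep the duration N (years of quarterly sampling) to find the
  minimum duration that pins each harmonic element inside the dense
  record's confidence interval.
* **Synthetic data:** a generator for sonde-like and
  manual-sample-like series with known harmonics, trend, diurnal
  cycle, AR(1) noise, gaps and spikes, so every stage has a
  parameter-recovery test surface.

## Worked example

```python
import coastharm as ch

# a coherent synthetic mainland-lagoon site: T, S, DO, Chl (daily, 10 yr)
suite = ch.generate_site_suite(seed=11)
aou = ch.derive_aou_series(suite["temperature"], suite["salinity"], suite["do"])

fit = ch.fit_harmonics(ch.to_climatology(suite["temperature"]))
comp = ch.composite_extrema(fit)
print(f"amplitude {comp.composite_amplitude:.2f} degC, "
      f"peak day {comp.date_of_max:.1f}, "
      f"annual variance fraction {fit.var_fraction[0]:.2f}")

trend = ch.gls_trend(ch.deseasonalize(suite["temperature"], fit))
print(f"trend {trend.slope:+.3f} degC/yr (p={trend.p_value:.2g})")
```

prints

```
amplitude 11.77 degC, peak day 213.5, annual variance fraction 0.96
trend +0.085 degC/yr (p=2.1e-06)
```

i.e. the seasonal cycle peaks in early August with an ~11.8 °C
amplitude dominated by the annual harmonic, and a significant warming
trend remains after the seasonal cycle is removed — both consistent
with the parameters this synthetic site was generated with (amplitude
11.8 °C peaking at day 214, trend +0.07 °C/yr).

The same stages are exposed as a CLI (`coastharm simulate | qc |
derive-aou | fit | trend | split-half | subsample-density |
subsample-duration | run`); `coastharm run --outdir out` executes the
whole pipeline and writes CSV tables, JSON summaries and a log of all
seeds.

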