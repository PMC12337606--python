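# Methods

## The model

The climatological seasonal cycle of a water-quality variable y is the
two-harmonic regression

    y^m(t) = ȳ + Σ_{k=1,2} [ a_k cos(2πkt/365) + b_k sin(2πkt/365) ]

with t the day of year on a fixed 365-day climatological calendar.
All individual observations are pooled across years and fitted by
ordinary least squares (not day-binned means): this uses the full
information in uneven records and weights each day of year by how
often it was actually sampled.  The method assumes (i) that most of
the seasonal variability is captured by the annual and semi-annual
harmonics, and (ii) that residuals after removing the climatology
drift gradually enough that a linear trend model is meaningful.

Derived per-harmonic elements are the amplitude C_k = √(a_k² + b_k²),
phase φ_k = atan2(b_k, a_k) and date of maximum
(365/2πk)·φ_k mapped into (0, 365/k].  The composite curve
(mean + both harmonics) is summarised by the dates and values of its
global maximum and minimum, found as zero-points of dy^m/dt (0.01-day
scan plus Brent refinement to |Δt| < 1e-8 d), and by the composite
seasonal amplitude, defined as half the max-minus-min range.  Equal
extrema (a pure semi-annual curve has two) report the earliest date
and set a multiplicity flag; a flat curve has undefined dates and
amplitude zero.

### Conventions

* **Day of year.** 1-based.  Leap years are squeezed onto the 365-day
  calendar: Feb 29 shares day 60 with Mar 1 and later days keep their
  non-leap numbering, so Dec 31 is always day 365 and the annual
  period is exactly 365 days.
* **Variance fractions.** Variance of a sinusoid of amplitude C is
  C²/2; the fraction for harmonic k is (C_k²/2)/Var(y) with the
  population variance of the pooled sample (so a noise-free sinusoid
  sampled on the full day grid scores exactly 1).  Fractions relative
  to the *fitted* variance only are also available
  (`variance_fractions(..., relative_to="fitted")`); dominant-harmonic
  selection uses the C_k² ratio, which is invariant to the choice.
* **Circular arithmetic.** Date elements live on a circle of period
  365 d (182.5 d for the semi-annual date).  Differences are reported
  in (−period/2, period/2]; bootstrap replicates and trial ensembles
  of dates are unwrapped around the point estimate before averaging
  or taking percentiles.

### Uncertainty

Confidence intervals for every fit and composite element come from a
case-resampling bootstrap (resample observations with replacement,
refit, percentile interval).  Case resampling was chosen over residual
resampling because seasonal heteroscedasticity — noisier summers than
winters, say — is the norm for these variables; residual resampling
would homogenise it.  Default n_boot = 1000, level 0.95.  The reduced
chi-squared Σ((y−y^m)/σ)²/(n−5) defaults σ to the residual SD of the
fit itself, which makes the statistic ≈1 by construction; it is only a
genuine goodness-of-fit measure when the caller supplies an
independent measurement σ.

## QC

* **Spike filter.** A point is dropped when it lies more than one
  standard deviation — computed from the raw values of its own
  calendar year — away from the *preceding retained* point, so a spike
  does not poison the baseline for its successors.  The first point is
  always kept.
* **Chauvenet's criterion.** Reject y_i when n·P(|Z| > |z_i|) < 0.5
  under a normal model with the sample mean and SD.  Single pass by
  default for determinism; an iterate-to-convergence switch exists
  because monitoring practice varies on this point.
* **Chlorophyll** is log10-transformed (standard for approximately
  log-normal bio-optical quantities); nonpositive values are dropped
  and counted.
* **Daily averaging** of sub-daily records removes the diurnal cycle;
  days with no retained samples are absent, and per-day sample counts
  are kept so users can apply their own completeness threshold (the
  default accepts any day with ≥ 1 sample).

QC only changes membership, never values, and all counts reconcile:
n_out = n_in − n_flagged.

## Oxygen

Saturation uses the Garcia–Gordon (1992) combined-fit polynomial in
scaled temperature Ts = ln[(298.15−T)/(273.15+T)] with the
Benson–Krause coefficients, valid for T ∈ [−2, 40] °C, S ∈ [0, 42].
The volumetric (mL/L) fit is the primary path, converted to mg/L via
the O2 molar mass 31.9988 g/mol and real-gas molar volume
22.3916 L/mol; the per-mass (µmol/kg) fit is exposed as an alternate
unit.  The volumetric-versus-per-mass convention changes mg/L results
by < 0.3 % (the density factor), well under sonde DO accuracy; the
volumetric path avoids needing a density model.  AOU = O2_sat − DO,
positive under net respiration.  No correction is attempted for
diurnal aliasing of AOU in low-frequency records; daily averaging
handles it for dense records.

## Trends

Deseasonalized anomalies y − y^m(doy) are regressed on time in
continuous years with AR(1)-GLS: an OLS pass estimates ρ from the
lag-1 autocorrelation of the residuals on the observation sequence,
then one GLS refit under that covariance gives slope, SE and two-sided
p-value (statsmodels GLSAR, two iterations).  AR(1) on the observation
sequence — rather than continuous time — is appropriate for the
near-regular quarterly records this targets; it understates
persistence for very gappy sub-daily records, which should be
daily-averaged first.  Multi-site mean trends propagate per-site slope
SEs as √(Σse_i²)/m assuming independent regressions.

Split-half analysis cuts a record (≥ 10 yr) at its temporal midpoint,
fits each half separately, and differences every harmonic and
composite element (dates circularly).  Shifts across groups of sites
are compared with Welch's unequal-variance t-test; both per-harmonic
and composite elements are emitted since either may be of interest.

## Subsampling experiments

Both experiments score sparse designs against a dense daily-averaged
reference record, whose fit, bootstrap CIs and anomaly SD (the SD of
its deseasonalized anomalies) form the truth surface.

* **Density-matched:** each of 200 trials draws the specified number
  of days uniformly without replacement within each calendar quarter
  (seasons = calendar quarters; Jan–Mar, …), refits, and is scored by
  RMSE = √(Σ_{i=1..365}(ref_i − trial_i)²/ν) between the two fitted
  curves on integer year-days, with ν the number of subsampled values
  in the trial as a degrees-of-freedom estimate; nRMSE divides by the
  reference anomaly SD; NSE = 1 − (RMSE/σ_trial)² with σ_trial the SD
  of the trial's sampled values (NSE ≥ 0.90 very good, 0.80–0.90
  good, 0.65–0.80 acceptable, < 0.65 unsatisfactory).
* **Duration sweep:** for each N in {5, 10, 15, 20, 25, 30, 40, 50}
  (years of quarterly sampling), trials draw N days per season from
  the record's pooled day-of-year distribution, without replacement
  within a trial.  Pooling across years makes N > record-length
  well-defined — a 50-year design can be scored against a 10-year
  reference because the climatological fit only consumes day-of-year.
  Trial-to-trial means and SDs of every element are tracked per N;
  the SDs are normalized (nSD) by their large-N asymptote, taken as
  the mean SD over the upper half of the N grid (trials are
  exchangeable, so an asymptote must come from the N direction, not a
  trial ordering).  The minimum adequate duration per element is the
  smallest N whose trial-mean element lies inside the reference
  bootstrap CI at two successive grid values; if never satisfied the
  closest N is reported with an `attained=False` flag.

The mechanism that makes minimum duration grow with noise: amplitude
and extremum estimates are nonlinear in the regression coefficients
and therefore biased upward at small sample sizes by O(σ²/(N·C)),
while the reference CI width scales as σ/√n_ref — so noisier
variables need proportionally longer records before the bias falls
inside the interval.  This is verified as a monotonicity property in
the test suite.

## Synthetic data

The generator emulates two observing modes: sonde-like series (any
pandas frequency alias, e.g. "15min" or "D") and manual-sample-like
series (cadence "quarterly": one sample mid-quarter at a fixed local
time-of-day, mimicking field protocols tied to a tidal phase).  A
series is mean + annual/semi-annual harmonics (amplitude and
date-of-maximum parametrization) + linear trend + optional diurnal
cosine (sonde mode) + AR(1) noise + random ±spike_scale·noise_sd
spikes, with gap windows removed afterwards.  AR(1) noise is generated
on the sampling grid, so ρ is per step (per-day ρ for 15-min data is
ρ_step⁹⁶); noise_sd is the innovation SD.  The noise structure of real
sonde records is not known to be AR(1); it is an assumption to vary in
sensitivity studies, not an inferred fact.

The multi-variable site suite generates T, S and chlorophyll from
their own configs on a shared time base and *constructs* DO as
o2_sat(T_obs, S_obs) − AOU_signal − noise, so the oxygen module
recovers the injected AOU cycle exactly in the noise-free limit.
Chlorophyll is log-normal: its config acts on the log10 scale and the
emitted series is 10^x.  Default suite parameters follow multi-decade
observations at shallow mid-Atlantic mainland-lagoon sites:
temperature 17 ± 11.8 °C amplitude peaking at day 214 with a
+0.07 °C/yr trend; salinity ~31 psu with mixed annual (0.9) and
semi-annual (0.7 psu) harmonics; AOU cycle of 0.8 mg/L amplitude
peaking at day 241; log10(Chl) amplitude 0.30.  What the generator
does **not** emulate: tidal (M2/S2) constituents, sensor drift and
biofouling, spatially correlated multi-site noise, and non-stationary
noise variance.  Passing recovery tests therefore demonstrates the
estimators are correct under the stated noise model, not that real
records satisfy that model.

## Problem sizes and numerical choices

Test and acceptance runs use 10-year daily synthetic records, 200
trials per subsampling condition, bootstrap sizes of 300–500 for
experiment CIs (1000 as the library default), 500 replicates for
coverage and calibration studies — sizes at which Monte-Carlo error is
comfortably below the tolerances asserted.  Extremum location is
verified against a 0.001-day brute-force grid; the Chauvenet mask
against a direct normal-tail computation; the solubility polynomial
against published check values (274.610 µmol/kg at 10 °C/35 psu and
the standard freshwater mg/L table).  Degenerate inputs are contracts,
not crashes: flat curves flag undefined dates, noise-free references
flag undefined nRMSE, sub-minimum record lengths raise informative
errors.

## Known limitations

* Fitting pools all years, so secular trends leak slightly into the
  climatology (and the anomaly mean); trend estimates remain unbiased
  because the leak is absorbed by the intercept.
* The spike filter's yearly SD uses raw (pre-filter) values, so a
  spike-heavy year has an inflated threshold; with the documented
  spike rates (< 10 %) the effect is second-order.
* GLS assumes AR(1) errors; long-memory or seasonal error structure
  would call for a richer covariance.
* The minimum-duration rule inherits the coarseness of the N grid.
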