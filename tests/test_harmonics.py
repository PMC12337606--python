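import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coastharm as ch
from coastharm.harmonics import (
    ClimatologySeries,
    YEAR_DAYS,
    _design_matrix,
    circular_delta,
    day_of_year_365,
)


def clim_from_curve(mean=10.0, a=(5.0, 0.0), b=(0.0, 0.0), noise=None, seed=0,
                    years=1):
    doy = np.tile(np.arange(1.0, 366.0), years)
    w = 2 * np.pi * doy / YEAR_DAYS
    y = mean + a[0] * np.cos(w) + b[0] * np.sin(w) \
        + a[1] * np.cos(2 * w) + b[1] * np.sin(2 * w)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(doy))
    return ClimatologySeries(day_of_year=doy, values=y)


def clim_peaked(mean, amps, dmaxes, noise=None, seed=0, years=1):
    """Climatology from amplitude/date-of-max parametrization."""
    doy = np.tile(np.arange(1.0, 366.0), years)
    w = 2 * np.pi / YEAR_DAYS
    y = np.full(len(doy), float(mean))
    for k, (C, d) in enumerate(zip(amps, dmaxes), start=1):
        y = y + C * np.cos(k * w * (doy - d))
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(doy))
    return ClimatologySeries(day_of_year=doy, values=y)


class TestDayOfYear:
    def test_jan1_is_day_1(self):
        assert day_of_year_365(pd.DatetimeIndex(["2021-01-01"]))[0] == 1

    def test_leap_day_and_march1_share_day_60(self):
        doy = day_of_year_365(pd.DatetimeIndex(["2020-02-29", "2020-03-01",
                                                "2021-03-01"]))
        assert list(doy) == [60, 60, 60]

    def test_dec31_always_day_365(self):
        doy = day_of_year_365(pd.DatetimeIndex(["2020-12-31", "2021-12-31"]))
        assert list(doy) == [365, 365]

    def test_ten_years_daily_covers_every_day(self, noisy_daily_10yr):
        clim = ch.to_climatology(noisy_daily_10yr)
        assert len(clim) == len(noisy_daily_10yr)
        assert set(np.unique(clim.day_of_year)) == set(range(1, 366))


class TestFitHarmonics:
    def test_exact_recovery_of_noisefree_annual_cycle(self):
        clim = clim_peaked(10.0, [5.0], [200.0])
        fit = ch.fit_harmonics(clim)
        assert fit.mean == pytest.approx(10.0, abs=1e-8)
        assert fit.amplitude[0] == pytest.approx(5.0, abs=1e-8)
        assert fit.date_of_max[0] == pytest.approx(200.0, abs=1e-8)
        assert fit.amplitude[1] == pytest.approx(0.0, abs=1e-8)

    def test_constant_series(self):
        clim = ClimatologySeries(np.arange(1.0, 366.0), np.full(365, 3.5))
        fit = ch.fit_harmonics(clim)
        assert fit.mean == pytest.approx(3.5)
        assert fit.amplitude == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_noisy_amplitude_recovery_within_analytic_se(self):
        # SE of an amplitude estimate is sigma * sqrt(2/N)
        amps = [ch.fit_harmonics(
                    clim_peaked(10.0, [5.0, 1.0], [200.0, 80.0],
                                noise=1.0, seed=s, years=10)
                ).amplitude[0]
                for s in range(50)]
        assert np.mean(amps) == pytest.approx(5.0, abs=0.1)
        assert np.std(amps) < 3 * np.sqrt(2 / 3650)

    def test_rank_deficient_design_rejected(self):
        clim = ClimatologySeries(np.array([1.0, 50, 100, 200] * 5),
                                 np.ones(20))
        with pytest.raises(ValueError, match="distinct day-of-year"):
            ch.fit_harmonics(clim)

    def test_residuals_orthogonal_to_basis(self):
        clim = clim_peaked(4.0, [2.0, 0.5], [120.0, 30.0], noise=0.8, seed=3,
                           years=3)
        fit = ch.fit_harmonics(clim)
        resid = clim.values - fit.predict(clim.day_of_year)
        X = _design_matrix(clim.day_of_year, 2)
        bound = 1e-6 * len(clim) * clim.values.std()
        assert np.all(np.abs(X.T @ resid) < bound)

    def test_fit_invariant_to_observation_order(self):
        clim = clim_peaked(4.0, [2.0, 0.5], [120.0, 30.0], noise=0.8, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(clim))
        fit_a = ch.fit_harmonics(clim)
        fit_b = ch.fit_harmonics(ClimatologySeries(
            clim.day_of_year[perm], clim.values[perm]))
        assert fit_a.amplitude == pytest.approx(fit_b.amplitude, abs=1e-10)
        assert fit_a.mean == pytest.approx(fit_b.mean, abs=1e-10)


class TestVarianceFractions:
    def test_pure_annual_sine_captures_all_variance(self):
        fit = ch.fit_harmonics(clim_peaked(0.0, [3.0], [100.0]))
        res = ch.variance_fractions(fit)
        assert res["fractions"][0] == pytest.approx(1.0, abs=1e-9)
        assert res["fractions"][1] == pytest.approx(0.0, abs=1e-9)
        assert res["dominant_harmonic"] == 1

    def test_equal_amplitudes_split_evenly(self):
        fit = ch.fit_harmonics(clim_peaked(0.0, [2.0, 2.0], [100.0, 50.0]))
        res = ch.variance_fractions(fit)
        assert res["fractions"] == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_two_to_one_amplitude_is_80_20(self):
        # variance of a sinusoid is C^2/2, so amplitudes 2:1 give 4/5 : 1/5
        fit = ch.fit_harmonics(clim_peaked(0.0, [2.0, 1.0], [100.0, 50.0]))
        res = ch.variance_fractions(fit)
        assert res["fractions"] == pytest.approx([0.8, 0.2], abs=1e-9)
        fitted = ch.variance_fractions(fit, relative_to="fitted")
        assert fitted["fractions"] == pytest.approx([0.8, 0.2], abs=1e-9)

    def test_fraction_sum_bounded_by_one(self, noisy_daily_10yr):
        fit = ch.fit_harmonics(ch.to_climatology(noisy_daily_10yr))
        assert fit.total_var_captured <= 1 + 1e-9


class TestCompositeExtrema:
    def test_single_harmonic_closed_form(self):
        fit = ch.fit_harmonics(clim_peaked(10.0, [5.0], [200.0]))
        comp = ch.composite_extrema(fit)
        assert comp.date_of_max == pytest.approx(200.0, abs=1e-6)
        assert comp.date_of_min == pytest.approx(17.5, abs=1e-6)
        assert comp.composite_amplitude == pytest.approx(5.0, abs=1e-9)

    def test_pure_semiannual_reports_earliest_of_equal_maxima(self):
        fit = ch.fit_harmonics(clim_peaked(0.0, [0.0, 3.0], [1.0, 40.0]))
        comp = ch.composite_extrema(fit)
        assert comp.multiple_maxima
        assert comp.date_of_max == pytest.approx(40.0, abs=1e-6)

    def test_flat_curve_flagged(self):
        fit = ch.fit_harmonics(ClimatologySeries(np.arange(1.0, 366.0),
                                                 np.full(365, 2.0)))
        comp = ch.composite_extrema(fit)
        assert comp.degenerate
        assert comp.composite_amplitude == 0.0

    def test_amplitude_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            amps = rng.uniform(0.1, 5, 2)
            fit = ch.fit_harmonics(clim_peaked(0.0, amps,
                                               rng.uniform(1, 365, 2)))
            comp = ch.composite_extrema(fit)
            assert comp.composite_amplitude >= abs(amps[0] - amps[1]) - 1e-9
            assert comp.composite_amplitude <= amps.sum() + 1e-9

    def test_agrees_with_brute_force_grid(self):
        # oracle: direct evaluation of the composite curve on a 0.001-d grid
        rng = np.random.default_rng(99)
        tgrid = np.arange(0.001, YEAR_DAYS + 0.001, 0.001)
        for _ in range(100):
            fit = ch.fit_harmonics(clim_from_curve(
                mean=rng.normal(), a=rng.normal(0, 2, 2),
                b=rng.normal(0, 2, 2)))
            comp = ch.composite_extrema(fit)
            y = fit.predict(tgrid)
            assert comp.date_of_max == pytest.approx(
                tgrid[np.argmax(y)], abs=0.01)
            assert comp.date_of_min == pytest.approx(
                tgrid[np.argmin(y)], abs=0.01)


class TestBootstrap:
    def test_noisefree_intervals_degenerate(self):
        clim = clim_peaked(10.0, [5.0, 1.0], [200.0, 80.0], years=1)
        ci = ch.bootstrap_fit(clim, n_boot=100, seed=0)
        for el in ("mean", "C1", "C2", "composite_amplitude"):
            assert ci.width(el) < 1e-8

    def test_fixed_seed_reproducible(self):
        clim = clim_peaked(10.0, [5.0], [200.0], noise=1.0, seed=1)
        a = ch.bootstrap_fit(clim, n_boot=50, seed=42)
        b = ch.bootstrap_fit(clim, n_boot=50, seed=42)
        assert a.intervals == b.intervals

    def test_interval_brackets_point_estimate(self):
        clim = clim_peaked(10.0, [5.0, 1.0], [200.0, 80.0], noise=1.5, seed=2,
                           years=3)
        ci = ch.bootstrap_fit(clim, n_boot=200, seed=3)
        for el in ("mean", "C1", "composite_amplitude", "date_of_max"):
            assert ci.contains(el, ci.point[el])

    def test_too_few_observations_rejected(self):
        clim = ClimatologySeries(np.arange(1.0, 16.0), np.ones(15))
        with pytest.raises(ValueError, match=">= 20"):
            ch.bootstrap_fit(clim, n_boot=10, seed=0)


class TestReducedChiSquared:
    def test_perfect_fit_is_zero(self):
        clim = clim_peaked(10.0, [5.0], [200.0])
        fit = ch.fit_harmonics(clim)
        assert ch.reduced_chi_squared(fit, clim, sigma=1.0) == pytest.approx(
            0.0, abs=1e-14)

    def test_correct_sigma_gives_unity(self):
        clim = clim_peaked(10.0, [5.0], [200.0], noise=1.0, seed=5, years=3)
        fit = ch.fit_harmonics(clim)
        assert ch.reduced_chi_squared(fit, clim, sigma=1.0) == pytest.approx(
            1.0, abs=0.1)

    def test_underestimated_sigma_scales_quadratically(self):
        clim = clim_peaked(10.0, [5.0], [200.0], noise=1.0, seed=6, years=3)
        fit = ch.fit_harmonics(clim)
        full = ch.reduced_chi_squared(fit, clim, sigma=1.0)
        half = ch.reduced_chi_squared(fit, clim, sigma=0.5)
        assert half == pytest.approx(4 * full, rel=1e-9)


class TestDeseasonalize:
    def test_model_generated_data_has_zero_anomalies(self, noisefree_daily):
        fit = ch.fit_harmonics(ch.to_climatology(noisefree_daily))
        anoms = ch.deseasonalize(noisefree_daily, fit)
        np.testing.assert_allclose(anoms.values, 0.0, atol=1e-8)

    def test_trend_survives_deseasonalizing(self):
        cfg = ch.SyntheticConfig(mean=10.0, amp1=5.0, dmax1=200, trend=0.05,
                                 cadence="D", start="2010-01-01",
                                 end="2019-12-31")
        s = ch.generate_series(cfg)
        fit = ch.fit_harmonics(ch.to_climatology(s))
        anoms = ch.deseasonalize(s, fit)
        slope = np.polyfit(np.arange(len(anoms)) / 365.25, anoms.values, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.005)

    def test_zero_mean_for_untrended_noisefree_input(self, noisefree_daily):
        fit = ch.fit_harmonics(ch.to_climatology(noisefree_daily))
        anoms = ch.deseasonalize(noisefree_daily, fit)
        assert abs(anoms.values.mean()) < 1e-6


@given(late=st.floats(0.001, 365), early=st.floats(0.001, 365))
@settings(max_examples=200, deadline=None)
def test_circular_delta_properties(late, early):
    d = circular_delta(late, early)
    assert -YEAR_DAYS / 2 < d <= YEAR_DAYS / 2
    # antisymmetry up to the boundary case at exactly half a period
    if abs(d) != YEAR_DAYS / 2:
        assert circular_delta(early, late) == pytest.approx(-d, abs=1e-9)
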