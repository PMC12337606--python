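import numpy as np
import pandas as pd
import pytest

import coastharm as ch


@pytest.fixture(scope="session")
def noisefree_daily():
    """One year of noise-free daily data: pure annual cycle, amp 5, peak day 200."""
    cfg = ch.SyntheticConfig(mean=10.0, amp1=5.0, dmax1=200, cadence="D",
                             start="2015-01-01", end="2015-12-31", seed=1)
    return ch.generate_series(cfg)


@pytest.fixture(scope="session")
def noisy_daily_10yr():
    """Ten years of daily data with both harmonics and iid noise."""
    cfg = ch.SyntheticConfig(mean=10.0, amp1=5.0, amp2=1.0, dmax1=200, dmax2=80,
                             noise_sd=2.0, ar1_rho=0.0, cadence="D",
                             start="2010-01-01", end="2019-12-31", seed=7)
    return ch.generate_series(cfg)


@pytest.fixture(scope="session")
def site_suite():
    """Coherent synthetic T/S/DO/Chl site with realistic noise."""
    return ch.generate_site_suite(seed=11)


@pytest.fixture
def quarterly_times():
    return pd.date_range("1990-02-15", periods=120, freq="91D")


def make_anomaly_series(times, values):
    return ch.SampleSeries(site="X", variable="anomaly", times=times,
                           values=np.asarray(values, dtype=float))
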