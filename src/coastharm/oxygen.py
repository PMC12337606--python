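"""Oxygen solubility and apparent oxygen utilization (AOU).

Saturation concentrations use the Garcia & Gordon (1992) combined fit
with the Benson & Krause coefficient data, evaluated in the scaled
temperature Ts = ln[(298.15 - T)/(273.15 + T)].  The volumetric fit
(mL/L) is the primary path here and is converted to mg/L with the O2
molar mass 31.9988 g/mol and real-gas molar volume 22.3916 L/mol at
STP; the per-mass (umol/kg) fit is also exposed.  The volumetric
convention matters at the <0.3% level relative to per-mass followed by
a density conversion, which is negligible against sonde DO accuracy.

AOU = O2_saturation(T, S) - DO_observed, so positive AOU is a net
oxygen deficit (net respiration signal), the convention under which
shallow-lagoon AOU peaks in summer.
"""

from __future__ import annotations

import numpy as np

from .series import SampleSeries

# Garcia & Gordon (1992) combined fit, Benson & Krause data, cm3/dm3 (mL/L)
_A_ML = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_B_ML = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_C_ML = -4.88682e-7

# same fit, umol/kg
_A_KG = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_B_KG = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_C_KG = -2.75915e-7

O2_MOLAR_MASS = 31.9988      # g/mol
O2_MOLAR_VOLUME = 22.3916    # L/mol at STP (real gas)
MG_PER_ML = O2_MOLAR_MASS / O2_MOLAR_VOLUME  # 1.42905 mg O2 per mL O2

T_RANGE = (-2.0, 40.0)
S_RANGE = (0.0, 42.0)


def _check_range(temperature, salinity) -> None:
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < T_RANGE[0]) or np.any(t > T_RANGE[1]):
        raise ValueError(f"temperature outside valid range {T_RANGE} degC")
    if np.any(s < S_RANGE[0]) or np.any(s > S_RANGE[1]):
        raise ValueError(f"salinity outside valid range {S_RANGE} psu")


def _garcia_gordon(temperature, salinity, A, B, C):
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))
    ln_c = np.polynomial.polynomial.polyval(ts, A)
    ln_c = ln_c + s * np.polynomial.polynomial.polyval(ts, B)
    ln_c = ln_c + C * s**2
    return np.exp(ln_c)


def o2_saturation(temperature, salinity, unit: str = "mg/L"):
    """Oxygen saturation concentration at in-situ temperature and salinity.

    Parameters
    ----------
    temperature : array_like
        In-situ temperature, -2..40 degC.
    salinity : array_like
        Practical salinity, 0..42 psu.
    unit : {'mg/L', 'mL/L', 'umol/kg'}
        Output unit.  'mg/L' (default) and 'mL/L' use the volumetric
        coefficient set; 'umol/kg' uses the per-mass set.
    """
    _check_range(temperature, salinity)
    if unit in ("mg/L", "mL/L"):
        ml = _garcia_gordon(temperature, salinity, _A_ML, _B_ML, _C_ML)
        return ml * MG_PER_ML if unit == "mg/L" else ml
    if unit == "umol/kg":
        return _garcia_gordon(temperature, salinity, _A_KG, _B_KG, _C_KG)
    raise ValueError(f"unknown unit {unit!r}")


def aou(temperature, salinity, do_obs):
    """Apparent oxygen utilization in mg/L: saturation minus observed DO."""
    do = np.asarray(do_obs, dtype=float)
    if np.any(do < 0):
        raise ValueError("observed dissolved oxygen must be >= 0")
    return o2_saturation(temperature, salinity) - do


def derive_aou_series(temperature: SampleSeries, salinity: SampleSeries,
                      do: SampleSeries) -> SampleSeries:
    """AOU series from co-located temperature, salinity and DO series.

    All three series must share an identical time base.
    """
    if not (temperature.times.equals(salinity.times)
            and temperature.times.equals(do.times)):
        raise ValueError("temperature, salinity and DO series must share a time base")
    values = aou(temperature.values, salinity.values, do.values)
    return SampleSeries(
        site=do.site,
        variable="aou",
        times=do.times,
        values=values,
        units="mg/L",
    )
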