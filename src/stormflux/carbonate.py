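"""Seawater carbonate system and air-sea CO2 gas exchange.

The air-sea flux follows

    F = k_w * S_CO2 * (pCO2_ocean - pCO2_atmo)        [positive upward]

with the gas transfer velocity k_w quadratic in the 10-m wind speed and
scaled by the Schmidt number (Wanninkhof 2014 coefficients), and the CO2
solubility S_CO2 from the Weiss (1974) fit. Surface-ocean pCO2 is obtained
from DIC and total alkalinity by solving the alkalinity balance (carbonate,
bicarbonate, borate, and water terms) for the hydrogen-ion concentration on
the total pH scale, using the OMIP-recommended equilibrium constants:
K1/K2 from Lueker et al. (2000), KB from Dickson (1990), KW from the
Dickson et al. (2007) refit, total boron from Uppstrom (1974).

All functions are pure and vectorized over numpy arrays. Internal carbon
units are mol/kg for speciation and mol m^-2 s^-1 for fluxes; the public
surface works in umol/kg and matm, with a helper to express fluxes in
mmolC m^-2 day^-1 (the display unit of the along-track diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

T_VALID = (-2.0, 40.0)  # degC
S_VALID = (0.0, 45.0)  # practical salinity
SLP_VALID = (870.0, 1085.0)  # hPa

SCHMIDT_REF = 660.0  # Sc of CO2 in seawater at 20 degC (normalization point)
# Wanninkhof (2014) quadratic-wind coefficient, cm/h per (m/s)^2
GAS_TRANSFER_COEF_CM_H = 0.251

SECONDS_PER_DAY = 86_400.0


class ConvergenceError(RuntimeError):
    """Raised when the carbonate solver fails to meet tolerance."""


def _check_range(name, value, lo, hi):
    v = np.asarray(value, dtype=float)
    if np.any(v < lo) or np.any(v > hi):
        raise ValueError(f"{name} outside validity range [{lo}, {hi}]")
    return v


# ---------------------------------------------------------------------------
# Gas exchange kinetics
# ---------------------------------------------------------------------------

def schmidt_number(t_c):
    """Schmidt number of CO2 in seawater (S=35), Wanninkhof (2014) polynomial.

    Sc = 2116.8 - 136.25 T + 4.7353 T^2 - 0.092307 T^3 + 0.0007555 T^4,
    T in degC, valid -2..40 degC. Strictly decreasing over the valid range.
    """
    t = _check_range("temperature", t_c, *T_VALID)
    return (2116.8 - 136.25 * t + 4.7353 * t ** 2
            - 0.092307 * t ** 3 + 0.0007555 * t ** 4)


def gas_transfer_velocity(u10, t_c):
    """Gas transfer velocity k_w in m/s.

    k_w = 0.251 * u10^2 * (Sc/660)^(-1/2) in cm/h (Wanninkhof 2014),
    converted to m/s. Exactly quadratic in wind at fixed temperature.
    """
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("u10 must be non-negative")
    sc = schmidt_number(t_c)
    kw_cm_h = GAS_TRANSFER_COEF_CM_H * u ** 2 * np.sqrt(SCHMIDT_REF / sc)
    return kw_cm_h * 0.01 / 3600.0


def co2_solubility(t_c, s):
    """CO2 solubility S_CO2 in mol m^-3 uatm^-1 (Weiss 1974, volumetric fit).

    ln K0 [mol/(L atm)] = -58.0931 + 90.5069*(100/T) + 22.2940*ln(T/100)
        + S*(0.027766 - 0.025888*(T/100) + 0.0050578*(T/100)^2),  T in K.
    Strictly decreasing in temperature at fixed salinity.
    """
    t = _check_range("temperature", t_c, *T_VALID)
    sal = _check_range("salinity", s, *S_VALID)
    tk100 = (t + 273.15) / 100.0
    ln_k0 = (-58.0931 + 90.5069 / tk100 + 22.2940 * np.log(tk100)
             + sal * (0.027766 - 0.025888 * tk100 + 0.0050578 * tk100 ** 2))
    k0_mol_l_atm = np.exp(ln_k0)
    # mol/(L atm) -> mol/(m^3 uatm): x1000 L/m^3, /1e6 uatm/atm
    return k0_mol_l_atm * 1.0e-3


# ---------------------------------------------------------------------------
# Equilibrium constants (total pH scale, mol/kg-SW)
# ---------------------------------------------------------------------------

def k0_weiss_gravimetric(t_c, s):
    """CO2 solubility in mol kg^-1 atm^-1 (Weiss 1974), for speciation."""
    tk100 = (np.asarray(t_c, dtype=float) + 273.15) / 100.0
    sal = np.asarray(s, dtype=float)
    ln_k0 = (-60.2409 + 93.4517 / tk100 + 23.3585 * np.log(tk100)
             + sal * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100 ** 2))
    return np.exp(ln_k0)


def k1_k2_lueker(t_c, s):
    """First and second carbonic acid dissociation constants, Lueker (2000)."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    sal = np.asarray(s, dtype=float)
    pk1 = (3633.86 / tk - 61.2172 + 9.6777 * np.log(tk)
           - 0.011555 * sal + 0.0001152 * sal ** 2)
    pk2 = (471.78 / tk + 25.929 - 3.16967 * np.log(tk)
           - 0.01781 * sal + 0.0001122 * sal ** 2)
    return 10.0 ** (-pk1), 10.0 ** (-pk2)


def kb_dickson(t_c, s):
    """Boric acid dissociation constant, Dickson (1990), total scale."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    sal = np.asarray(s, dtype=float)
    sqs = np.sqrt(sal)
    ln_kb = ((-8966.90 - 2890.53 * sqs - 77.942 * sal
              + 1.728 * sal * sqs - 0.0996 * sal ** 2) / tk
             + 148.0248 + 137.1942 * sqs + 1.62142 * sal
             + (-24.4344 - 25.085 * sqs - 0.2474 * sal) * np.log(tk)
             + 0.053105 * sqs * tk)
    return np.exp(ln_kb)


def kw_water(t_c, s):
    """Ion product of water, Dickson et al. (2007) refit, total scale."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    sal = np.asarray(s, dtype=float)
    ln_kw = (148.9652 - 13847.26 / tk - 23.6521 * np.log(tk)
             + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * np.sqrt(sal)
             - 0.01615 * sal)
    return np.exp(ln_kw)


def total_boron(s):
    """Total boron in mol/kg from salinity (Uppstrom 1974)."""
    return 0.0004157 * np.asarray(s, dtype=float) / 35.0


def fugacity_factor(t_c):
    """fCO2/pCO2 ratio from the CO2 virial coefficients (Weiss 1974)."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    b = -1636.75 + 12.0408 * tk - 3.27957e-2 * tk ** 2 + 3.16528e-5 * tk ** 3
    delta = 57.7 - 0.118 * tk
    rt = 82.05736 * tk  # cm^3 atm / mol
    return np.exp((b + 2.0 * delta) / rt)


# ---------------------------------------------------------------------------
# Carbonate-system solution
# ---------------------------------------------------------------------------

@dataclass
class CarbonateState:
    """Surface carbonate state at a point (arrays allowed in every field)."""

    temperature: np.ndarray  # degC
    salinity: np.ndarray
    dic: np.ndarray  # umol/kg
    alkalinity: np.ndarray  # umol/kg
    pco2: np.ndarray  # uatm
    h_ion: np.ndarray  # mol/kg, total scale
    solubility: np.ndarray  # mol m^-3 uatm^-1 (volumetric, for flux)

    @property
    def ph(self):
        return -np.log10(self.h_ion)


@dataclass
class AtmosphereCO2:
    """Atmospheric CO2 boundary condition."""

    xco2_ppm: float  # dry-air mole fraction
    slp_hpa: np.ndarray = 1013.25  # sea-level pressure

    def __post_init__(self):
        if np.any(np.asarray(self.xco2_ppm) <= 0):
            raise ValueError("CO2 mole fraction must be positive")
        _check_range("sea-level pressure", self.slp_hpa, *SLP_VALID)

    def pco2_uatm(self, t_c, s):
        """pCO2^atmo = xCO2 * (SLP - saturation water vapor pressure)."""
        return self.xco2_ppm * (
            np.asarray(self.slp_hpa, dtype=float) / 1013.25
            - vapor_pressure_atm(t_c, s))


def vapor_pressure_atm(t_c, s):
    """Saturation water vapor pressure over seawater in atm (Weiss & Price 1980)."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    sal = np.asarray(s, dtype=float)
    return np.exp(24.4543 - 67.4509 * (100.0 / tk)
                  - 4.8489 * np.log(tk / 100.0) - 0.000544 * sal)


def _alkalinity_from_h(h, dic_molkg, k1, k2, kb, kw, bt):
    """Total alkalinity (mol/kg) implied by [H+] and DIC."""
    denom = h * h + k1 * h + k1 * k2
    carb_alk = dic_molkg * (k1 * h + 2.0 * k1 * k2) / denom
    return carb_alk + bt * kb / (kb + h) + kw / h - h


def _validate_dic_alk(dic, alk):
    if np.any(dic <= 0):
        raise ValueError("DIC must be positive")
    if np.any(alk <= dic) or np.any(alk >= 2.0 * dic):
        raise ValueError("require DIC < Alk < 2*DIC (valid seawater ordering)")


def solve_carbonate(dic, alk, t_c, s, max_iter=100, tol_umolkg=1e-3):
    """Solve the carbonate system for pCO2 from DIC and total alkalinity.

    Parameters are in umol/kg (DIC, Alk), degC, practical salinity; arrays
    broadcast. The hydrogen-ion concentration is found by safeguarded
    bisection on pH in [3, 12]; convergence is declared when the alkalinity
    balance is met within ``tol_umolkg``.

    Returns a :class:`CarbonateState`. Raises :class:`ConvergenceError` if
    the tolerance is not met within ``max_iter`` iterations.
    """
    dic = np.asarray(dic, dtype=float)
    alk = np.asarray(alk, dtype=float)
    _validate_dic_alk(dic, alk)
    t = _check_range("temperature", t_c, *T_VALID)
    sal = _check_range("salinity", s, *S_VALID)

    dic_m = dic * 1e-6
    alk_m = alk * 1e-6
    k1, k2 = k1_k2_lueker(t, sal)
    kb = kb_dickson(t, sal)
    kw = kw_water(t, sal)
    bt = total_boron(sal)

    shape = np.broadcast_shapes(dic_m.shape, alk_m.shape,
                                np.shape(k1), np.shape(kb))
    lo = np.full(shape, 1e-12)  # pH 12
    hi = np.full(shape, 1e-3)  # pH 3
    h = None
    for _ in range(max_iter):
        h = np.sqrt(lo * hi)  # bisection in log space
        resid = _alkalinity_from_h(h, dic_m, k1, k2, kb, kw, bt) - alk_m
        if np.max(np.abs(resid)) * 1e6 < tol_umolkg:
            break
        # alkalinity is monotone decreasing in [H+]
        too_alkaline = resid > 0  # implied alk too high -> H too small
        lo = np.where(too_alkaline, h, lo)
        hi = np.where(too_alkaline, hi, h)
    else:
        resid = _alkalinity_from_h(h, dic_m, k1, k2, kb, kw, bt) - alk_m
        if np.max(np.abs(resid)) * 1e6 >= tol_umolkg:
            raise ConvergenceError(
                f"alkalinity residual {np.max(np.abs(resid)) * 1e6:.3g} umol/kg "
                f"after {max_iter} iterations")

    co2_star = dic_m * h * h / (h * h + k1 * h + k1 * k2)
    k0 = k0_weiss_gravimetric(t, sal)
    fco2 = co2_star / k0 * 1e6  # uatm
    pco2 = fco2 / fugacity_factor(t)
    return CarbonateState(
        temperature=t, salinity=sal, dic=dic, alkalinity=alk,
        pco2=pco2, h_ion=h, solubility=co2_solubility(t, sal))


def dic_from_pco2(pco2, alk, t_c, s, max_iter=100, tol_umolkg=1e-3):
    """Invert the carbonate system: DIC (umol/kg) from pCO2 and alkalinity."""
    pco2 = np.asarray(pco2, dtype=float)
    alk_m = np.asarray(alk, dtype=float) * 1e-6
    t = _check_range("temperature", t_c, *T_VALID)
    sal = _check_range("salinity", s, *S_VALID)
    k1, k2 = k1_k2_lueker(t, sal)
    kb = kb_dickson(t, sal)
    kw = kw_water(t, sal)
    bt = total_boron(sal)
    k0 = k0_weiss_gravimetric(t, sal)
    co2_star = k0 * fugacity_factor(t) * pco2 * 1e-6  # mol/kg

    shape = np.broadcast_shapes(pco2.shape, alk_m.shape, np.shape(k1))
    lo = np.full(shape, 1e-12)
    hi = np.full(shape, 1e-3)
    for _ in range(max_iter):
        h = np.sqrt(lo * hi)
        ta = (co2_star * (k1 / h + 2.0 * k1 * k2 / (h * h))
              + bt * kb / (kb + h) + kw / h - h)
        resid = ta - alk_m
        if np.max(np.abs(resid)) * 1e6 < tol_umolkg:
            break
        too_alkaline = resid > 0
        lo = np.where(too_alkaline, h, lo)
        hi = np.where(too_alkaline, hi, h)
    else:
        raise ConvergenceError("DIC inversion did not converge")

    dic_m = co2_star * (1.0 + k1 / h + k1 * k2 / (h * h))
    return dic_m * 1e6


# ---------------------------------------------------------------------------
# Flux
# ---------------------------------------------------------------------------

@dataclass
class FluxResult:
    """Air-sea CO2 flux, positive upward (ocean outgassing)."""

    kw_ms: np.ndarray  # gas transfer velocity, m/s
    flux_mol_m2_s: np.ndarray

    @property
    def flux_mmol_m2_day(self):
        return self.flux_mol_m2_s * 1e3 * SECONDS_PER_DAY


def air_sea_co2_flux(kw_ms, s_co2, pco2_ocean, pco2_atmo):
    """F = k_w * S_CO2 * (pCO2_ocean - pCO2_atmo), positive upward.

    kw in m/s, S_CO2 in mol m^-3 uatm^-1, pCO2 in uatm; F in mol m^-2 s^-1.
    Exactly linear (and antisymmetric) in the pCO2 disequilibrium.
    """
    kw = np.asarray(kw_ms, dtype=float)
    sco2 = np.asarray(s_co2, dtype=float)
    if np.any(kw < 0):
        raise ValueError("gas transfer velocity must be non-negative")
    if np.any(sco2 <= 0):
        raise ValueError("solubility must be positive")
    flux = kw * sco2 * (np.asarray(pco2_ocean, dtype=float)
                        - np.asarray(pco2_atmo, dtype=float))
    return FluxResult(kw_ms=kw, flux_mol_m2_s=flux)
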