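"""Independent oracles used by the test suite.

The carbonate oracle solves the same chemistry as the package but by a
different route: it parameterizes the system by pH, computes the implied DIC
analytically from the alkalinity balance, and root-finds on pH with Brent's
method (scipy). The equilibrium-constant fits are transcribed here
independently from their published forms (Lueker et al. 2000; Dickson 1990;
Dickson et al. 2007; Weiss 1974; Uppstrom 1974) so a transcription slip in
the package does not silently cancel.
"""

import numpy as np
from scipy.optimize import brentq


def _k1_k2(t_c, s):
    tk = t_c + 273.15
    pk1 = (3633.86 / tk - 61.2172 + 9.6777 * np.log(tk)
           - 0.011555 * s + 0.0001152 * s * s)
    pk2 = (471.78 / tk + 25.929 - 3.16967 * np.log(tk)
           - 0.01781 * s + 0.0001122 * s * s)
    return 10.0 ** -pk1, 10.0 ** -pk2


def _kb(t_c, s):
    tk = t_c + 273.15
    rt = np.sqrt(s)
    return np.exp(
        (-8966.90 - 2890.53 * rt - 77.942 * s + 1.728 * s * rt
         - 0.0996 * s * s) / tk
        + 148.0248 + 137.1942 * rt + 1.62142 * s
        + (-24.4344 - 25.085 * rt - 0.2474 * s) * np.log(tk)
        + 0.053105 * rt * tk)


def _kw(t_c, s):
    tk = t_c + 273.15
    return np.exp(148.9652 - 13847.26 / tk - 23.6521 * np.log(tk)
                  + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * np.sqrt(s)
                  - 0.01615 * s)


def _k0_gravimetric(t_c, s):
    q = (t_c + 273.15) / 100.0
    return np.exp(-60.2409 + 93.4517 / q + 23.3585 * np.log(q)
                  + s * (0.023517 - 0.023656 * q + 0.0047036 * q * q))


def _fugacity_factor(t_c):
    tk = t_c + 273.15
    b = -1636.75 + 12.0408 * tk - 3.27957e-2 * tk ** 2 + 3.16528e-5 * tk ** 3
    delta = 57.7 - 0.118 * tk
    return np.exp((b + 2.0 * delta) / (82.05736 * tk))


def pco2_oracle(dic_umolkg, alk_umolkg, t_c, s):
    """pCO2 (uatm) by pH-parameterized solution + Brent root-finding."""
    dic = dic_umolkg * 1e-6
    alk = alk_umolkg * 1e-6
    k1, k2 = _k1_k2(t_c, s)
    kb = _kb(t_c, s)
    kw = _kw(t_c, s)
    bt = 0.0004157 * s / 35.0

    def co2_star_of_ph(ph):
        h = 10.0 ** -ph
        carb_alk = alk - bt * kb / (kb + h) - kw / h + h
        return carb_alk / (k1 / h + 2.0 * k1 * k2 / (h * h)), h

    def dic_mismatch(ph):
        co2, h = co2_star_of_ph(ph)
        return co2 * (1.0 + k1 / h + k1 * k2 / (h * h)) - dic

    ph = brentq(dic_mismatch, 3.0, 12.0, xtol=1e-12)
    co2, _ = co2_star_of_ph(ph)
    fco2 = co2 / _k0_gravimetric(t_c, s) * 1e6
    return fco2 / _fugacity_factor(t_c)


def circle_mean_bruteforce(values_2d, lat, lon, center, radius_km, areas):
    """Area-weighted circle mean by explicit per-cell enumeration."""
    earth_r = 6371.0
    la0, lo0 = np.radians(center[0]), np.radians(center[1])
    total = 0.0
    wsum = 0.0
    for i in range(len(lat)):
        for j in range(len(lon)):
            la, lo = np.radians(lat[i]), np.radians(lon[j])
            a = (np.sin((la - la0) / 2) ** 2
                 + np.cos(la0) * np.cos(la) * np.sin((lo - lo0) / 2) ** 2)
            d = 2 * earth_r * np.arcsin(min(1.0, np.sqrt(a)))
            if d <= radius_km:
                total += values_2d[i, j] * areas[i, j]
                wsum += areas[i, j]
    return total / wsum if wsum > 0 else np.nan
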