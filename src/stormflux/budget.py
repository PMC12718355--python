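"""Tracer-budget closure, temperature-dependent remineralization, and the
export-ratio diagnostic.

The tendency of a tracer C is decomposed as

    dC/dt = -U_h . grad(C) - w dC/dz + d/dz(k_v dC/dz)
            + surface fluxes + biogeochemical sources and sinks

and the residual (tendency minus the sum of the terms) measures closure.
Remineralization follows a Q10 law, R = r0 * Q10^((T - T_ref)/10) * C; the
temperature counterfactual recomputes R with temperatures frozen to their
pre-storm profile, isolating the temperature-driven change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TERM_NAMES = ("h_adv", "v_adv", "v_diff", "surface", "bio")


@dataclass
class BudgetTerms:
    """All terms share units (tracer per time) and shape."""

    tendency: np.ndarray
    h_adv: np.ndarray
    v_adv: np.ndarray
    v_diff: np.ndarray
    surface: np.ndarray
    bio: np.ndarray

    def terms_sum(self):
        return (self.h_adv + self.v_adv + self.v_diff
                + self.surface + self.bio)

    @property
    def residual(self):
        return self.tendency - self.terms_sum()


def budget_residual(terms: BudgetTerms):
    """Pointwise residual plus a normalized summary.

    Returns (residual array, summary dict with max|residual|,
    max|tendency| and their ratio). Raises listing any missing term.
    """
    missing = [n for n in ("tendency",) + TERM_NAMES
               if getattr(terms, n, None) is None]
    if missing:
        raise ValueError(f"missing budget terms: {missing}")
    res = terms.residual
    max_res = float(np.max(np.abs(res)))
    max_tend = float(np.max(np.abs(terms.tendency)))
    summary = {"max_abs_residual": max_res, "max_abs_tendency": max_tend,
               "normalized_residual": (max_res / max_tend if max_tend > 0
                                       else 0.0)}
    return res, summary


@dataclass
class ReminParams:
    """Q10 remineralization: rate = r0 * Q10^((T - T_ref)/10) * substrate."""

    r0_per_day: float = 0.03
    q10: float = 2.0
    t_ref_c: float = 10.0

    def __post_init__(self):
        if self.r0_per_day <= 0:
            raise ValueError("reference rate must be positive")
        if self.q10 < 1.0:
            raise ValueError("Q10 must be >= 1")


def remineralization_rate(substrate, t_c, params: ReminParams):
    """Remineralization rate in substrate units per day."""
    sub = np.asarray(substrate, dtype=float)
    if np.any(sub < 0):
        raise ValueError("substrate concentration must be non-negative")
    t = np.asarray(t_c, dtype=float)
    return params.r0_per_day * params.q10 ** ((t - params.t_ref_c) / 10.0) * sub


def _integrate_to(depth_m, values, horizon_m):
    """Trapezoidal vertical integral from the surface to ``horizon_m``,
    with the endpoint interpolated linearly inside the last cell."""
    z = np.asarray(depth_m, dtype=float)
    v = np.asarray(values, dtype=float)
    if horizon_m > z[-1]:
        raise ValueError(f"integration horizon {horizon_m} m exceeds the "
                         f"deepest level {z[-1]} m")
    inside = z <= horizon_m
    z_in = z[inside]
    v_in = v[..., inside]
    if z_in[-1] < horizon_m:
        v_end = np.apply_along_axis(
            lambda col: np.interp(horizon_m, z, col), -1, v)
        z_in = np.append(z_in, horizon_m)
        v_in = np.concatenate([v_in, v_end[..., None]], axis=-1)
    return np.trapezoid(v_in, z_in, axis=-1)


def temperature_counterfactual(substrate, t_actual, t_pre, depth_m,
                               params: ReminParams,
                               horizons_m=(100.0, 1000.0)):
    """Temperature-driven remineralization change and its vertical integrals.

    ``substrate`` and ``t_actual`` have shape (..., nz) over the time window
    (leading axes arbitrary); ``t_pre`` is the pre-storm temperature profile
    (nz,). Returns (delta_r, integrals) where
    delta_r = R(T_actual) - R(T_pre) pointwise, and ``integrals`` maps each
    horizon to the trapezoidal vertical integral of delta_r.
    """
    r_actual = remineralization_rate(substrate, t_actual, params)
    r_pre = remineralization_rate(substrate, np.asarray(t_pre, dtype=float),
                                  params)
    delta = r_actual - r_pre
    integrals = {float(hz): _integrate_to(depth_m, delta, hz)
                 for hz in horizons_m}
    return delta, integrals


def export_ratio(times_days, npp, export, lag_days=9.0, window=None):
    """Integrated export (lagged) over integrated NPP.

    ratio = int[export(t + lag)] dt / int[NPP(t)] dt over ``window``
    (a (start_day, end_day) pair in the units of ``times_days``; default the
    longest window for which the lagged export series exists).
    """
    t = np.asarray(times_days, dtype=float)
    nppv = np.asarray(npp, dtype=float)
    expv = np.asarray(export, dtype=float)
    if window is None:
        window = (t[0], t[-1] - lag_days)
    w0, w1 = window
    if w1 + lag_days > t[-1] + 1e-9:
        raise ValueError("series too short for the requested window + lag")
    sel = (t >= w0) & (t <= w1)
    if not sel.any():
        raise ValueError("empty integration window")
    exp_lagged = np.interp(t[sel] + lag_days, t, expv)
    npp_int = np.trapezoid(nppv[sel], t[sel])
    exp_int = np.trapezoid(exp_lagged, t[sel])
    if npp_int == 0:
        raise ZeroDivisionError("integrated NPP is zero; ratio undefined")
    return exp_int / npp_int
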