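"""Translating parametric hurricane vortex: wind and pressure snapshots.

The radial structure follows Holland (1980): with shape parameter B and
radius of maximum wind R_mw,

    p(r)  = p_c + (p_env - p_c) * exp(-(R_mw/r)^B)
    V(r)  = V_max * sqrt((R_mw/r)^B * exp(1 - (R_mw/r)^B))

so the wind peaks exactly at R_mw with value V_max and the pressure rises
monotonically to the environmental value. The central pressure deficit is
tied to intensity through the Holland relation
Delta_p = rho_air * e * V_max^2 / B. Beyond five R_mw the tangential wind is
damped with a 3-R_mw e-folding so the storm's dynamical footprint stays
bounded; the pressure field needs no such envelope.

Intensity evolves along a piecewise-linear ramp of (time, V_max) nodes and
the center follows piecewise-linear track waypoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import RHO_AIR
from .grid import RegularGrid, normalize_lon

WIND_ENVELOPE_START_RMW = 5.0  # radii of maximum wind
WIND_ENVELOPE_EFOLD_RMW = 3.0
PRESSURE_ENVELOPE_RMW = 8.0  # Gaussian scale of the pressure-deficit taper
HURRICANE_MIN_MS = 33.0
TS_MIN_MS = 17.0


def _as_times(times):
    return np.array([np.datetime64(t, "s") for t in times])


@dataclass
class VortexSpec:
    """One storm: waypoints, intensity ramp, and radial-structure parameters.

    waypoints: sequence of (time, lat, lon); at least two, strictly
        increasing times; the center moves linearly between them.
    vmax_ramp: sequence of (time, V_max m/s); piecewise-linear in time.
    r_mw_km: radius of maximum wind.
    p_env_hpa: environmental pressure.
    holland_b: Holland shape parameter; central pressure is derived as
        p_c = p_env - rho_air * e * V_max^2 / (100 * B) hPa.
    """

    waypoints: list
    vmax_ramp: list
    r_mw_km: float = 40.0
    p_env_hpa: float = 1013.0
    holland_b: float = 1.4

    def __post_init__(self):
        wp = [(np.datetime64(t, "s"), float(la), float(normalize_lon(lo)))
              for t, la, lo in self.waypoints]
        if len(wp) < 2:
            raise ValueError("need at least two track waypoints")
        times = np.array([t for t, _, _ in wp])
        if not np.all(np.diff(times).astype(float) > 0):
            raise ValueError("waypoint times must be strictly increasing")
        self.waypoints = wp
        ramp = [(np.datetime64(t, "s"), float(v)) for t, v in self.vmax_ramp]
        if any(v < 0 for _, v in ramp):
            raise ValueError("V_max must be non-negative")
        self.vmax_ramp = ramp
        if self.r_mw_km <= 0:
            raise ValueError("R_mw must be positive")
        # hurricane-strength storms must carry a real pressure deficit
        for _, v in ramp:
            if v > TS_MIN_MS and self.central_pressure_hpa(v) >= self.p_env_hpa:
                raise ValueError("central pressure must undercut environment "
                                 "for storm-force winds")

    @classmethod
    def constant_motion(cls, genesis_time, genesis_lat, genesis_lon,
                        u_east_ms, v_north_ms, duration_h, vmax_ms,
                        ramp_up_h=24.0, **kwargs):
        """Straight-moving storm: ramp to vmax_ms over ramp_up_h, then hold."""
        t0 = np.datetime64(genesis_time, "s")
        t1 = t0 + np.timedelta64(int(duration_h * 3600), "s")
        # convert m/s to deg/h at genesis latitude
        dlat_h = v_north_ms * 3600.0 / 111_195.0
        dlon_h = (u_east_ms * 3600.0 /
                  (111_195.0 * max(0.2, np.cos(np.radians(genesis_lat)))))
        wps = [(t0, genesis_lat, genesis_lon),
               (t1, genesis_lat + dlat_h * duration_h,
                genesis_lon + dlon_h * duration_h)]
        tr = t0 + np.timedelta64(int(min(ramp_up_h, duration_h) * 3600), "s")
        ramp = [(t0, min(vmax_ms, 15.0)), (tr, vmax_ms), (t1, vmax_ms)]
        return cls(waypoints=wps, vmax_ramp=ramp, **kwargs)

    # -- time-dependent state -------------------------------------------------
    @property
    def t_start(self):
        return self.waypoints[0][0]

    @property
    def t_end(self):
        return self.waypoints[-1][0]

    def active(self, time) -> bool:
        t = np.datetime64(time, "s")
        return self.t_start <= t <= self.t_end

    def position(self, time):
        """(lat, lon) of the center; linear interpolation between waypoints."""
        t = np.datetime64(time, "s").astype(float)
        times = np.array([w[0] for w in self.waypoints]).astype(float)
        lats = np.array([w[1] for w in self.waypoints])
        lons = np.unwrap(np.radians([w[2] for w in self.waypoints]))
        lat = float(np.interp(t, times, lats))
        lon = float(normalize_lon(np.degrees(np.interp(t, times, lons))))
        return lat, lon

    def vmax(self, time) -> float:
        t = np.datetime64(time, "s").astype(float)
        times = np.array([r[0] for r in self.vmax_ramp]).astype(float)
        vals = np.array([r[1] for r in self.vmax_ramp])
        return float(np.interp(t, times, vals))

    def central_pressure_hpa(self, vmax_ms) -> float:
        dp_pa = RHO_AIR * np.e * vmax_ms ** 2 / self.holland_b
        return self.p_env_hpa - dp_pa / 100.0

    def translation_velocity(self, time):
        """(u_east, v_north) m/s of the center motion at a given time."""
        dt = np.timedelta64(1800, "s")
        t = np.datetime64(time, "s")
        t0 = max(self.t_start, t - dt)
        t1 = min(self.t_end, t + dt)
        (la0, lo0), (la1, lo1) = self.position(t0), self.position(t1)
        secs = float((t1 - t0).astype(float))
        if secs == 0:
            return 0.0, 0.0
        v = (la1 - la0) * 111_195.0 / secs
        u = ((lo1 - lo0 + 180.0) % 360.0 - 180.0) * 111_195.0 * \
            np.cos(np.radians((la0 + la1) / 2.0)) / secs
        return u, v


def holland_profile(r_km, vmax_ms, r_mw_km, p_env_hpa, p_c_hpa, b):
    """Radial wind (m/s) and pressure (hPa) at distance r from the center."""
    r = np.maximum(np.asarray(r_km, dtype=float), 1e-6)
    x = (r_mw_km / r) ** b
    wind = vmax_ms * np.sqrt(x * np.exp(1.0 - x))
    # outer envelope: damp the far-field tail so the storm stays compact
    beyond = np.maximum(0.0, r - WIND_ENVELOPE_START_RMW * r_mw_km)
    wind = wind * np.exp(-beyond / (WIND_ENVELOPE_EFOLD_RMW * r_mw_km))
    # Holland's r^-B pressure tail is long; taper the deficit so the far
    # field returns to the environment within ~10 R_mw
    deficit = (p_env_hpa - p_c_hpa) * (1.0 - np.exp(-x)) \
        * np.exp(-(r / (PRESSURE_ENVELOPE_RMW * r_mw_km)) ** 2)
    pres = p_env_hpa - deficit
    return wind, pres


def make_vortex_snapshot(specs, time, grid: RegularGrid):
    """MSLP (hPa) and wind (m/s) fields for one or more vortices at a time.

    Storms outside their life windows contribute nothing; if none is active
    the returned fields are environmental (uniform pressure, zero wind) and
    ``n_active`` reports 0. Pressure deficits of multiple storms add;
    winds combine by elementwise maximum.
    """
    if isinstance(specs, VortexSpec):
        specs = [specs]
    p_env = specs[0].p_env_hpa if specs else 1013.0
    mslp = np.full(grid.shape, p_env)
    wind = np.zeros(grid.shape)
    n_active = 0
    for spec in specs:
        if not spec.active(time):
            continue
        vmax = spec.vmax(time)
        lat0, lon0 = spec.position(time)
        if vmax <= 0:
            n_active += 1
            continue
        p_c = spec.central_pressure_hpa(vmax)
        r = grid.distances_km(lat0, lon0)
        w, p = holland_profile(r, vmax, spec.r_mw_km, spec.p_env_hpa, p_c,
                               spec.holland_b)
        mslp += p - spec.p_env_hpa
        wind = np.maximum(wind, w)
        n_active += 1
    return mslp, wind, n_active
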