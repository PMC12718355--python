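"""Along-track and column diagnostics.

Composites are means over a 200-km-radius circle of grid cells whose centers
lie within the radius, cell-area-weighted by default. "Passage time" at a
location is the time of closest approach of the track center. The wake
delta of a field is its circle average 24 h after passage minus 24 h
before, at a circle fixed on the track point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import constants as c
from .grid import FieldSeries, haversine_km
from .tracking import CycloneTrack


def _track_arrays(track):
    """(times, lats, lons) from a CycloneTrack or a track DataFrame."""
    if isinstance(track, CycloneTrack):
        return track.times, track.lats, track.lons
    df = track
    return (df["time"].values.astype("datetime64[s]"),
            df["lat"].values.astype(float), df["lon"].values.astype(float))


def translation_speed(track) -> np.ndarray:
    """Along-track translation speed (m/s) per point.

    Centered great-circle differences over the native point spacing;
    one-sided at the endpoints.
    """
    times, lats, lons = _track_arrays(track)
    n = len(times)
    if n < 2:
        raise ValueError("translation speed needs at least two track points")
    speed = np.empty(n)
    for i in range(n):
        j0, j1 = max(0, i - 1), min(n - 1, i + 1)
        dist_m = haversine_km(lats[j0], lons[j0], lats[j1], lons[j1]) * 1000.0
        dt_s = float((times[j1] - times[j0]).astype("timedelta64[s]")
                     .astype(float))
        speed[i] = dist_m / dt_s
    return speed


def circle_average(fields: FieldSeries, var: str, center, time=None,
                   radius_km=c.CIRCLE_RADIUS_KM, area_weighted=True):
    """Cell-area-weighted mean of ``var`` over a great-circle disc.

    ``center`` is (lat, lon). With ``time=None`` the average is returned for
    every time step (1-D array); otherwise for the nearest snapshot. An
    empty circle yields NaN with a warning.
    """
    lat0, lon0 = center
    dist = fields.grid.distances_km(lat0, lon0)
    mask = dist <= radius_km
    if not mask.any():
        warnings.warn("circle contains no grid cells; returning NaN")
        return np.nan
    w = fields.cell_areas_m2()[mask] if area_weighted else np.ones(mask.sum())
    da = fields[var]
    if time is not None:
        da = da.sel(time=time, method="nearest")
        vals = da.values[mask]
        return float(np.average(vals, weights=w))
    vals = da.values[:, mask]
    return np.average(vals, axis=1, weights=w)


def wake_delta(fields: FieldSeries, var: str, track,
               lead_h=c.WAKE_LEAD_H, lag_h=c.WAKE_LAG_H,
               radius_km=c.CIRCLE_RADIUS_KM) -> pd.DataFrame:
    """Per-track-point change: circle mean at (t + lag) minus at (t - lead).

    The circle stays fixed at the track point. Points whose window is not
    covered by the field series get NaN.
    """
    times, lats, lons = _track_arrays(track)
    t_axis = fields.times
    out = []
    for t, la, lo in zip(times, lats, lons):
        t_before = t - np.timedelta64(int(lead_h * 3600), "s")
        t_after = t + np.timedelta64(int(lag_h * 3600), "s")
        if t_before < t_axis[0] or t_after > t_axis[-1]:
            out.append(np.nan)
            continue
        v_after = circle_average(fields, var, (la, lo), time=t_after,
                                 radius_km=radius_km)
        v_before = circle_average(fields, var, (la, lo), time=t_before,
                                  radius_km=radius_km)
        out.append(v_after - v_before)
    return pd.DataFrame({"time": times, "lat": lats, "lon": lons,
                         "delta": out})


def wake_semicircle_delta(fields: FieldSeries, var: str, track,
                          lead_h=c.WAKE_LEAD_H, lag_h=c.WAKE_LAG_H,
                          radius_km=c.CIRCLE_RADIUS_KM) -> pd.DataFrame:
    """Wake delta split into right and left semicircles of the storm motion.

    Returns per-point right and left semicircle deltas and their difference;
    a negative ``right_minus_left`` means stronger cooling (for SST) on the
    right-hand side of the track.
    """
    times, lats, lons = _track_arrays(track)
    t_axis = fields.times
    speeds = translation_speed(track)
    lat2d, lon2d = fields.grid.mesh
    areas = fields.cell_areas_m2()
    rows = []
    n = len(times)
    for i in range(n):
        t, la, lo = times[i], lats[i], lons[i]
        t_before = t - np.timedelta64(int(lead_h * 3600), "s")
        t_after = t + np.timedelta64(int(lag_h * 3600), "s")
        if t_before < t_axis[0] or t_after > t_axis[-1] or speeds[i] == 0:
            rows.append((t, la, lo, np.nan, np.nan))
            continue
        j0, j1 = max(0, i - 1), min(n - 1, i + 1)
        ev = lats[j1] - lats[j0]
        eu = ((lons[j1] - lons[j0] + 180.0) % 360.0 - 180.0) \
            * np.cos(np.radians(la))
        norm = np.hypot(eu, ev)
        eu, ev = eu / norm, ev / norm
        dx = np.radians((lon2d - lo + 180.0) % 360.0 - 180.0) \
            * np.cos(np.radians(lat2d)) * 6371.0
        dy = np.radians(lat2d - la) * 6371.0
        in_circle = fields.grid.distances_km(la, lo) <= radius_km
        cross = eu * dy - ev * dx  # > 0 on the left of motion
        field = fields[var]
        delta2d = (field.sel(time=t_after, method="nearest").values
                   - field.sel(time=t_before, method="nearest").values)
        halves = []
        for side_mask in (in_circle & (cross < 0), in_circle & (cross > 0)):
            if side_mask.any():
                halves.append(float(np.average(delta2d[side_mask],
                                               weights=areas[side_mask])))
            else:
                halves.append(np.nan)
        rows.append((t, la, lo, halves[0], halves[1]))
    df = pd.DataFrame(rows, columns=["time", "lat", "lon", "right", "left"])
    df["right_minus_left"] = df["right"] - df["left"]
    return df


def along_track_diagram(fields: FieldSeries, var: str, track,
                        radius_km=c.CIRCLE_RADIUS_KM,
                        anomaly=False,
                        anomaly_ref_offset_h=c.ANOMALY_REF_OFFSET_H
                        ) -> xr.DataArray:
    """Time series of the circle average at every track point.

    Returns a DataArray with dims (point, time) and coordinates
    ``lat``/``lon``/``passage_time`` along ``point``. With ``anomaly=True``
    the value at (passage time - offset) is subtracted per point.
    """
    times, lats, lons = _track_arrays(track)
    t_axis = fields.times
    rows = np.full((len(times), len(t_axis)), np.nan)
    for i, (t, la, lo) in enumerate(zip(times, lats, lons)):
        rows[i] = circle_average(fields, var, (la, lo), radius_km=radius_km)
        if anomaly:
            t_ref = t - np.timedelta64(int(anomaly_ref_offset_h * 3600), "s")
            if t_ref >= t_axis[0]:
                j = int(np.argmin(np.abs(t_axis - t_ref)))
                rows[i] = rows[i] - rows[i, j]
            else:
                rows[i] = np.nan
    return xr.DataArray(
        rows, dims=("point", "time"),
        coords={"time": t_axis, "lat": ("point", lats),
                "lon": ("point", lons),
                "passage_time": ("point", times)},
        name=f"{var}_anomaly" if anomaly else var,
        attrs={"radius_km": radius_km})


def fold_increase(fields: FieldSeries, flux_var: str, track,
                  baseline_window, radius_km=c.CIRCLE_RADIUS_KM) -> pd.DataFrame:
    """|circle-mean flux at passage| over the baseline mean |circle-mean flux|.

    ``baseline_window`` is a (start, end) pair of datetimes disjoint from the
    passage; the baseline is the time mean of the absolute circle-mean flux
    at the same circle. A zero baseline flags the ratio as NaN.
    """
    times, lats, lons = _track_arrays(track)
    t_axis = fields.times
    b0, b1 = (np.datetime64(b, "s") for b in baseline_window)
    sel = (t_axis >= b0) & (t_axis <= b1)
    if not sel.any():
        raise ValueError("baseline window does not intersect the time axis")
    folds = []
    for t, la, lo in zip(times, lats, lons):
        if b0 <= t <= b1:
            raise ValueError("baseline window must be disjoint from passage")
        series = circle_average(fields, flux_var, (la, lo),
                                radius_km=radius_km)
        base = np.mean(np.abs(series[sel]))
        j = int(np.argmin(np.abs(t_axis - t)))
        if base == 0:
            warnings.warn("zero baseline flux; fold-increase undefined")
            folds.append(np.nan)
        else:
            folds.append(abs(series[j]) / base)
    return pd.DataFrame({"time": times, "lat": lats, "lon": lons,
                         "fold": folds})


def integrate_track_region(fields: FieldSeries, flux_var: str, track,
                           radius_km=c.CIRCLE_RADIUS_KM, window=None):
    """Time- and area-integrated carbon mass in the moving track circle.

    The flux variable must carry a ``units`` attribute of
    ``mmolC m-2 day-1`` (positive up). At every field time step inside the
    track's lifetime (or ``window``), cells within ``radius_km`` of the
    interpolated track position contribute flux * area * dt. Returns
    (total TgC, footprint area m^2); the footprint is the union of all
    circles, each cell counted once.
    """
    units = fields[flux_var].attrs.get("units")
    if units is None:
        raise ValueError(f"flux variable {flux_var!r} carries no units")
    if "mmol" not in units.lower():
        raise ValueError(f"expected flux in mmolC m-2 day-1, got {units!r}")
    times, lats, lons = _track_arrays(track)
    t_axis = fields.times
    t0, t1 = times[0], times[-1]
    if window is not None:
        t0, t1 = (np.datetime64(w, "s") for w in window)
    sel = (t_axis >= t0) & (t_axis <= t1)
    dt_days = fields.time_step_seconds / 86400.0
    areas = fields.cell_areas_m2()
    tf = times.astype("datetime64[s]").astype(float)

    total_mmol = 0.0
    footprint = np.zeros(fields.grid.shape, dtype=bool)
    flux_all = fields[flux_var].values
    for k in np.flatnonzero(sel):
        t = t_axis[k].astype("datetime64[s]").astype(float)
        la = float(np.interp(t, tf, lats))
        lo = float(np.interp(t, tf, lons))
        mask = fields.grid.distances_km(la, lo) <= radius_km
        footprint |= mask
        total_mmol += float(np.sum(flux_all[k][mask] * areas[mask])) * dt_days
    total_tgc = total_mmol * 1e-3 * c.MOLAR_MASS_C / c.GRAMS_PER_TGC
    return total_tgc, float(areas[footprint].sum())


def cumulative_flux(diagram: xr.DataArray,
                    start_offset_h=c.CUMFLUX_START_OFFSET_H) -> xr.DataArray:
    """Running time integral of an along-track flux diagram per track point.

    Integration starts at (passage time + start_offset); earlier times are
    masked. For a flux in mmolC m^-2 day^-1 the result is in mmolC m^-2.
    """
    t_axis = diagram["time"].values
    dt_days = (float(np.diff(t_axis).astype("timedelta64[s]")[0]
                     .astype(float)) / 86400.0)
    out = np.full(diagram.shape, np.nan)
    for i in range(diagram.sizes["point"]):
        t_start = (diagram["passage_time"].values[i]
                   + np.timedelta64(int(start_offset_h * 3600), "s"))
        sel = t_axis >= t_start
        vals = diagram.values[i, sel]
        out[i, sel] = np.cumsum(vals) * dt_days
    res = diagram.copy(data=out)
    res.name = f"{diagram.name}_cumulative"
    return res


# ---------------------------------------------------------------------------
# Column diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    """Vertical profiles at one location; depths positive down, increasing."""

    depth_m: np.ndarray
    density: np.ndarray | None = None
    temperature: np.ndarray | None = None
    salinity: np.ndarray | None = None
    kv: np.ndarray | None = None

    def __post_init__(self):
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if not np.all(np.diff(self.depth_m) > 0):
            raise ValueError("depths must be strictly increasing")
        if self.kv is not None and np.any(np.asarray(self.kv) < 0):
            raise ValueError("vertical diffusivity must be non-negative")


def mixed_layer_depth(depth_m, density, threshold_kgm3) -> float:
    """Depth at which density first exceeds the surface value by ``threshold``.

    Linear interpolation between the bracketing levels; the bottom depth is
    returned when the threshold is never exceeded. ``density`` may be
    (nz,) or (..., nz); the depth axis is last.
    """
    z = np.asarray(depth_m, dtype=float)
    if not np.all(np.diff(z) > 0):
        raise ValueError("depths must be strictly increasing")
    rho = np.asarray(density, dtype=float)
    excess = rho - rho[..., :1] - threshold_kgm3

    def _one(ex):
        idx = np.flatnonzero(ex >= 0)
        if len(idx) == 0:
            return float(z[-1])
        i = idx[0]
        if i == 0:
            return float(z[0])
        # linear interpolation between level i-1 (below threshold) and i
        frac = -ex[i - 1] / (ex[i] - ex[i - 1])
        return float(z[i - 1] + frac * (z[i] - z[i - 1]))

    if excess.ndim == 1:
        return _one(excess)
    flat = excess.reshape(-1, len(z))
    return np.array([_one(e) for e in flat]).reshape(excess.shape[:-1])


def brunt_vaisala(depth_m, density, rho_ref=c.RHO_SEAWATER):
    """N^2 = (g/rho_ref) d(rho)/dz at interior levels, centered differences.

    Returns (depth_mid, n2); the sign is preserved (negative = unstable).
    With z positive down and density increasing downward, N^2 is positive.
    """
    z = np.asarray(depth_m, dtype=float)
    rho = np.asarray(density, dtype=float)
    if len(z) < 2:
        raise ValueError("Brunt-Vaisala needs at least two levels")
    drho_dz = np.gradient(rho, z, axis=-1)
    n2 = c.GRAVITY / rho_ref * drho_dz
    return z, n2


def inertial_period(lat_deg) -> float:
    """Local inertial period 2*pi/f in hours, f = 2*Omega*sin|lat|.

    Returns infinity at the equator (f = 0) with a warning.
    """
    lat = float(lat_deg)
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude must lie in [-90, 90] degrees")
    f = 2.0 * c.EARTH_OMEGA * np.sin(np.radians(abs(lat)))
    if f == 0.0:
        warnings.warn("inertial period is infinite at the equator")
        return np.inf
    return 2.0 * np.pi / f / 3600.0


def fraction_of(part, total, percent=True) -> float:
    """|part/total| as a percentage (ratio utility for carbon integrals)."""
    ratio = abs(float(part) / float(total))
    return 100.0 * ratio if percent else ratio
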