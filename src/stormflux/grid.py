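"""Regular latitude-longitude grid geometry and the FieldSeries container.

All distances are great-circle (haversine) on a sphere of radius 6,371 km.
Longitudes are normalized to [-180, 180). Cell areas come from spherical
geometry: A = R^2 * dlon * (sin(lat_n) - sin(lat_s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .constants import EARTH_RADIUS_M


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; broadcasts over array inputs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.minimum(1.0, np.sqrt(a)))


@dataclass(frozen=True)
class RegularGrid:
    """Regular lat-lon grid defined by 1-D coordinate centers (degrees)."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", normalize_lon(self.lon))
        if self.lat.ndim != 1 or self.lon.ndim != 1:
            raise ValueError("lat and lon must be 1-D coordinate arrays")
        if len(self.lat) > 1 and not np.all(np.diff(self.lat) > 0):
            raise ValueError("lat must be strictly increasing")

    @classmethod
    def from_bounds(cls, lat_min, lat_max, lon_min, lon_max, spacing_deg):
        lat = np.arange(lat_min, lat_max + spacing_deg / 2.0, spacing_deg)
        lon = np.arange(lon_min, lon_max + spacing_deg / 2.0, spacing_deg)
        return cls(lat=lat, lon=lon)

    @property
    def shape(self):
        return (len(self.lat), len(self.lon))

    @property
    def mesh(self):
        """(lat2d, lon2d) cell-center meshes."""
        return np.meshgrid(self.lat, self.lon, indexing="ij")

    @property
    def spacing_deg(self):
        dlat = float(np.diff(self.lat).mean()) if len(self.lat) > 1 else 1.0
        return dlat

    def cell_areas_m2(self):
        """Spherical cell areas, shape (nlat, nlon)."""
        dlat = np.gradient(self.lat) if len(self.lat) > 1 else np.array([1.0])
        dlon = np.gradient(self.lon) if len(self.lon) > 1 else np.array([1.0])
        lat_n = np.radians(self.lat + dlat / 2.0)
        lat_s = np.radians(self.lat - dlat / 2.0)
        band = EARTH_RADIUS_M ** 2 * (np.sin(lat_n) - np.sin(lat_s))
        return np.outer(band, np.radians(dlon))

    def distances_km(self, lat0, lon0):
        """Great-circle distance from (lat0, lon0) to every cell center."""
        lat2d, lon2d = self.mesh
        return haversine_km(lat0, lon0, lat2d, lon2d)


class FieldSeries:
    """Time x lat x lon surface fields with grid geometry and unit metadata.

    Thin wrapper around an ``xarray.Dataset`` with dims (time, lat, lon).
    Flux variables carry a ``positive`` attribute; the internal convention is
    positive upward (ocean to atmosphere).
    """

    def __init__(self, ds: xr.Dataset):
        for dim in ("time", "lat", "lon"):
            if dim not in ds.dims and dim not in ds.coords:
                raise ValueError(f"FieldSeries requires a '{dim}' coordinate")
        self.ds = ds
        self.grid = RegularGrid(lat=ds["lat"].values, lon=ds["lon"].values)

    @classmethod
    def from_arrays(cls, times, grid: RegularGrid, variables: dict,
                    attrs: dict | None = None):
        """Build from a dict of name -> (array(time,lat,lon), attrs_dict)."""
        data_vars = {}
        for name, (arr, vattrs) in variables.items():
            data_vars[name] = (("time", "lat", "lon"), np.asarray(arr), dict(vattrs))
        ds = xr.Dataset(
            data_vars,
            coords={"time": np.asarray(times), "lat": grid.lat, "lon": grid.lon},
            attrs=dict(attrs or {}),
        )
        ds["lat"].attrs.setdefault("units", "degrees_north")
        ds["lon"].attrs.setdefault("units", "degrees_east")
        return cls(ds)

    # -- convenience accessors -------------------------------------------------
    @property
    def times(self):
        return self.ds["time"].values

    @property
    def time_step_seconds(self):
        t = self.times
        if len(t) < 2:
            raise ValueError("need at least two time steps")
        dt = np.diff(t).astype("timedelta64[s]").astype(float)
        if not np.allclose(dt, dt[0]):
            raise ValueError("time axis is not uniform")
        return float(dt[0])

    def __getitem__(self, name) -> xr.DataArray:
        return self.ds[name]

    def __contains__(self, name):
        return name in self.ds

    @property
    def data_vars(self):
        return list(self.ds.data_vars)

    def cell_areas_m2(self):
        return self.grid.cell_areas_m2()

    def sel_time(self, time, method="nearest") -> xr.Dataset:
        return self.ds.sel(time=time, method=method)
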