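"""File formats, configuration hashing, and provenance.

Fields travel as CF-style netCDF (dims time/lat/lon, units attributes, flux
variables marked ``positive: up``); tracks as CSV with ISO-8601 times, with
an optional GeoJSON LineString export. Every written artifact embeds the
configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import FieldSeries

TRACK_COLUMNS = ["track_id", "time", "lat", "lon", "mslp_hPa", "vmax_ms",
                 "category"]


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_attrs(seed=None, cfg_hash=None) -> dict:
    from . import __version__
    attrs = {"stormflux_version": __version__}
    if seed is not None:
        attrs["seed"] = int(seed)
    if cfg_hash is not None:
        attrs["config_hash"] = cfg_hash
    return attrs


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------

def write_fields(fields: FieldSeries, path, seed=None, cfg_hash=None):
    """Write a FieldSeries as NETCDF3 with CF time encoding."""
    ds = fields.ds.copy()
    ds.attrs.update(provenance_attrs(seed, cfg_hash))
    t0 = pd.Timestamp(ds["time"].values[0]).isoformat()
    encoding = {"time": {"units": f"hours since {t0}", "dtype": "float64"}}
    for v in ds.data_vars:
        encoding[v] = {"_FillValue": np.float32(np.nan), "dtype": "float32"}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_fields(path) -> FieldSeries:
    """Read a CF netCDF file into a FieldSeries.

    Validates coordinates and units; flux variables declared
    ``positive: down`` are negated to the internal positive-up convention.
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    for dim in ("time", "lat", "lon"):
        if dim not in ds.coords:
            raise ValueError(f"input file lacks the '{dim}' coordinate")
    for v in ds.data_vars:
        if "units" not in ds[v].attrs:
            raise ValueError(f"variable {v!r} carries no units attribute")
        positive = ds[v].attrs.get("positive")
        if positive == "down":
            ds[v] = -ds[v]
            ds[v].attrs["positive"] = "up"
    return FieldSeries(ds)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def write_tracks(tracks_df: pd.DataFrame, path, seed=None, cfg_hash=None):
    """Track table to CSV (ISO-8601 times, provenance in a comment header)."""
    df = tracks_df.copy()
    if "category" not in df and "vmax_ms" in df:
        from .tracking import saffir_simpson_category
        df["category"] = [saffir_simpson_category(w) for w in df["vmax_ms"]]
    df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w") as fh:
        fh.write(f"# stormflux tracks; {json.dumps(provenance_attrs(seed, cfg_hash))}\n")
        df[TRACK_COLUMNS].to_csv(fh, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    try:
        df["time"] = pd.to_datetime(df["time"]).values.astype("datetime64[s]")
    except (ValueError, TypeError) as err:
        raise ValueError(f"malformed time values in {path}: {err}") from None
    return df


def tracks_to_geojson(tracks_df: pd.DataFrame, path=None):
    """One GeoJSON LineString feature per track, with summary properties."""
    features = []
    for tid, g in tracks_df.groupby("track_id"):
        g = g.sort_values("time")
        coords = [[float(lo), float(la)] for lo, la in zip(g["lon"], g["lat"])]
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {
                "track_id": int(tid),
                "start": str(pd.Timestamp(g["time"].iloc[0]).isoformat()),
                "end": str(pd.Timestamp(g["time"].iloc[-1]).isoformat()),
                "lmi_ms": float(g["vmax_ms"].max()),
                "min_mslp_hPa": float(g["mslp_hPa"].min()),
            },
        })
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh, indent=1)
    return gj
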