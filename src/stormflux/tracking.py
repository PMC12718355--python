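"""Tropical-cyclone detection, track stitching, and filtering.

The tracker works from 2-D snapshots of mean sea-level pressure and surface
wind speed. Candidate points are MSLP minima below 1,010 hPa, found by
iteratively taking the global minimum and masking an 800-km disc around it.
Candidates with winds of at least tropical-storm force (17 m/s) are stitched
into tracks by a greedy nearest-in-time rule: starting from the earliest
candidate in the genesis latitude band, the track is extended to the first
subsequent snapshot (within 24 h) containing a qualifying point within
100 km; ties at the same time step are broken by lowest MSLP and the losing
points are removed from the pool. Retained tracks must have a lifetime
strictly greater than 24 h and a lifetime-maximum intensity strictly above
hurricane strength (33 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import constants as c
from .grid import FieldSeries, RegularGrid, haversine_km


class CandidatePoint(NamedTuple):
    time: np.datetime64
    lat: float
    lon: float
    mslp_hpa: float
    wind_ms: float


@dataclass
class CycloneTrack:
    """Ordered candidate points forming one cyclone track."""

    points: list[CandidatePoint]

    def __post_init__(self):
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times).astype(float) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def times(self):
        return np.array([p.time for p in self.points], dtype="datetime64[s]")

    @property
    def lats(self):
        return np.array([p.lat for p in self.points])

    @property
    def lons(self):
        return np.array([p.lon for p in self.points])

    @property
    def winds(self):
        return np.array([p.wind_ms for p in self.points])

    @property
    def mslps(self):
        return np.array([p.mslp_hpa for p in self.points])

    @property
    def lifetime_h(self) -> float:
        t = self.times
        return float((t[-1] - t[0]).astype("timedelta64[s]").astype(float)) / 3600.0

    @property
    def lmi_ms(self) -> float:
        """Lifetime-maximum intensity (peak along-track wind)."""
        return float(self.winds.max())

    @property
    def category(self) -> str:
        return saffir_simpson_category(self.lmi_ms)

    def __len__(self):
        return len(self.points)

    def to_dataframe(self, track_id=0) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": track_id,
            "time": self.times,
            "lat": self.lats,
            "lon": self.lons,
            "mslp_hPa": self.mslps,
            "vmax_ms": self.winds,
            "category": [saffir_simpson_category(w) for w in self.winds],
        })


def saffir_simpson_category(wind_ms) -> str:
    """Saffir-Simpson label for a sustained surface wind speed in m/s.

    Hurricane categories start at 33 m/s (category 1); category 4 at 58 m/s;
    category 5 at 70 m/s. Below 17 m/s is a tropical depression, 17-33 m/s a
    tropical storm.
    """
    w = float(wind_ms)
    if w < 0:
        raise ValueError("wind speed must be non-negative")
    label = "tropical depression"
    if w >= c.TROPICAL_STORM_MS:
        label = "tropical storm"
    for cat in sorted(c.SAFFIR_SIMPSON_MS):
        if w >= c.SAFFIR_SIMPSON_MS[cat]:
            label = f"category {cat}"
    return label


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------

def detect_candidates(mslp_hpa, wind_ms, grid: RegularGrid, time,
                      p_threshold_hpa=c.MSLP_CANDIDATE_THRESHOLD_HPA,
                      mask_radius_km=c.CANDIDATE_MASK_RADIUS_KM,
                      wind_radius_km=c.CANDIDATE_WIND_RADIUS_KM,
                      ) -> list[CandidatePoint]:
    """Candidate TC points in one MSLP/wind snapshot.

    Iteratively selects the global MSLP minimum while it is strictly below
    ``p_threshold_hpa``, records it as a candidate, masks all cells within
    ``mask_radius_km``, and repeats. The candidate's wind is the maximum
    wind within ``wind_radius_km`` of the pressure minimum (wind maxima sit
    at the radius of maximum wind, not at the center).
    """
    mslp = np.asarray(mslp_hpa, dtype=float)
    wind = np.asarray(wind_ms, dtype=float)
    if mslp.shape != grid.shape or wind.shape != grid.shape:
        raise ValueError("snapshot shapes do not match the grid")

    work = mslp.copy()
    out: list[CandidatePoint] = []
    while True:
        idx = np.unravel_index(np.nanargmin(work), work.shape)
        pmin = work[idx]
        if not pmin < p_threshold_hpa:
            break
        lat0 = grid.lat[idx[0]]
        lon0 = grid.lon[idx[1]]
        dist = grid.distances_km(lat0, lon0)
        vmax = float(np.nanmax(np.where(dist <= wind_radius_km, wind, np.nan)))
        out.append(CandidatePoint(np.datetime64(time, "s"), float(lat0),
                                  float(lon0), float(pmin), vmax))
        work[dist <= mask_radius_km] = np.inf
        if not np.isfinite(work).any():
            break
    return out


def detect_all_candidates(fields: FieldSeries, mslp_var="mslp", wind_var="wind",
                          **kwargs) -> list[CandidatePoint]:
    """Run candidate detection on every snapshot of a FieldSeries."""
    out = []
    for t in fields.times:
        snap = fields.ds.sel(time=t)
        out.extend(detect_candidates(snap[mslp_var].values, snap[wind_var].values,
                                     fields.grid, t, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def _in_genesis_band(lat, band, hemisphere):
    lo, hi = band
    if hemisphere == "north":
        return lo <= lat <= hi
    return lo <= abs(lat) <= hi


def stitch_tracks(candidates: Sequence[CandidatePoint],
                  wind_min_ms=c.STITCH_WIND_MIN_MS,
                  link_radius_km=c.LINK_RADIUS_KM,
                  link_window_h=c.LINK_WINDOW_H,
                  genesis_band=c.GENESIS_LAT_BAND,
                  hemisphere="both") -> list[CycloneTrack]:
    """Greedily stitch candidate points into cyclone tracks.

    Only candidates at or above ``wind_min_ms`` participate. Track starts are
    the earliest remaining candidates inside the genesis latitude band
    (``hemisphere='both'`` reads the band as absolute latitude). Extension
    searches snapshot by snapshot from the next time step out to
    ``link_window_h`` (inclusive), stopping at the first snapshot with any
    point within ``link_radius_km`` (inclusive); among same-time matches the
    lowest MSLP wins and the other matches are removed from the pool.
    """
    pool = [p for p in candidates if p.wind_ms >= wind_min_ms]
    # deterministic ordering regardless of storage order: time, mslp, lat, lon
    pool.sort(key=lambda p: (p.time.astype("datetime64[s]").astype(int),
                             p.mslp_hpa, p.lat, p.lon))
    alive = list(pool)
    tracks: list[CycloneTrack] = []

    while True:
        starts = [p for p in alive
                  if _in_genesis_band(p.lat, genesis_band, hemisphere)]
        if not starts:
            break
        head = starts[0]  # earliest time; lowest MSLP among ties (sorted)
        alive.remove(head)
        points = [head]
        while True:
            t_head = points[-1].time
            later_times = sorted({p.time for p in alive if
                                  0 < _hours(p.time, t_head) <= link_window_h})
            extended = False
            for t_next in later_times:  # priority to points closer in time
                matches = [p for p in alive if p.time == t_next and
                           haversine_km(points[-1].lat, points[-1].lon,
                                        p.lat, p.lon) <= link_radius_km]
                if matches:
                    best = min(matches, key=lambda p: p.mslp_hpa)
                    points.append(best)
                    for p in matches:  # winner consumed, losers removed
                        alive.remove(p)
                    extended = True
                    break
            if not extended:
                break
        tracks.append(CycloneTrack(points=points))
    return tracks


def _hours(t1, t0):
    return float((t1 - t0).astype("timedelta64[s]").astype(float)) / 3600.0


def filter_tracks(tracks: Sequence[CycloneTrack],
                  min_lifetime_h=c.TRACK_MIN_LIFETIME_H,
                  min_lmi_ms=c.TRACK_MIN_LMI_MS) -> list[CycloneTrack]:
    """Retain tracks with lifetime > 24 h and LMI > hurricane strength.

    Both inequalities are strict: a 24.0-h lifetime or a 33.0 m/s LMI is
    removed.
    """
    return [t for t in tracks
            if t.lifetime_h > min_lifetime_h and t.lmi_ms > min_lmi_ms]


def track_fields(fields: FieldSeries, **kwargs) -> list[CycloneTrack]:
    """Full pipeline: detect, stitch, filter on a FieldSeries."""
    detect_keys = {"p_threshold_hpa", "mask_radius_km", "wind_radius_km",
                   "mslp_var", "wind_var"}
    stitch_keys = {"wind_min_ms", "link_radius_km", "link_window_h",
                   "genesis_band", "hemisphere"}
    filter_keys = {"min_lifetime_h", "min_lmi_ms"}
    unknown = set(kwargs) - detect_keys - stitch_keys - filter_keys
    if unknown:
        raise TypeError(f"unknown tracking options: {sorted(unknown)}")
    cands = detect_all_candidates(
        fields, **{k: v for k, v in kwargs.items() if k in detect_keys})
    tracks = stitch_tracks(
        cands, **{k: v for k, v in kwargs.items() if k in stitch_keys})
    return filter_tracks(
        tracks, **{k: v for k, v in kwargs.items() if k in filter_keys})


def tracks_to_dataframe(tracks: Sequence[CycloneTrack]) -> pd.DataFrame:
    frames = [t.to_dataframe(track_id=i) for i, t in enumerate(tracks)]
    if not frames:
        return pd.DataFrame(columns=["track_id", "time", "lat", "lon",
                                     "mslp_hPa", "vmax_ms", "category"])
    return pd.concat(frames, ignore_index=True)
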