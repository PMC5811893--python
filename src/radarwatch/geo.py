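"""Geodesic primitives and track kinematics.

All positions are decimal-degree WGS84 latitude/longitude; distances are
great-circle (haversine) kilometres on a sphere of mean radius 6371.0088 km.
At the scales that matter here (vessel matching below ~6 km, trip ranges of
hundreds to thousands of km) the sphere-vs-ellipsoid error is below 0.5% and
irrelevant next to GPS and interpolation error.

Timestamps are UTC seconds (integers) throughout the library; ISO-8601 only
at file boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "Fix",
    "haversine_km",
    "pairwise_haversine_km",
    "bearing_deg",
    "track_kinematics",
    "straightness",
    "interpolate_position",
    "interpolate_track",
]


def _normalize_lon(lon: float) -> float:
    """Map longitude into [-180, 180)."""
    return ((lon + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees; longitude normalized to [-180, 180)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError(f"non-finite coordinate: lat={self.lat}, lon={self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", _normalize_lon(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


@dataclass(frozen=True)
class Fix:
    """A timestamped position (t: UTC seconds)."""

    t: int
    pos: GeoPoint


def pairwise_haversine_km(lat1, lon1, lat2, lon2):
    """Vectorized haversine distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    if not (np.all(np.isfinite(lat1)) and np.all(np.isfinite(lon1))
            and np.all(np.isfinite(lat2)) and np.all(np.isfinite(lon2))):
        raise ValueError("non-finite coordinate in haversine input")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    # clip guards rounding at antipodes
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, km."""
    return float(pairwise_haversine_km(a.lat, a.lon, b.lat, b.lon))


def bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees clockwise
    from true north in [0, 360). Undefined (NaN) for coincident points."""
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(lon2 - lon1)
    y = np.sin(dlmb) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlmb)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    same = (lat1 == lat2) & (np.abs(np.asarray(lon1) - np.asarray(lon2)) % 360.0 == 0.0)
    return np.where(same, np.nan, brg)


def _wrap_turn(dh):
    """Wrap a heading difference into (-180, 180]."""
    w = ((np.asarray(dh, dtype=float) + 180.0) % 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def track_kinematics(t, lat, lon) -> pd.DataFrame:
    """Per-segment kinematics of an ordered track.

    Returns one row per segment, assigned to the segment's *end* fix: columns
    ``t`` (end time, s), ``dt_s``, ``dist_km``, ``speed_kmh``, ``heading_deg``
    and ``turn_angle_deg``. Headings of zero-length segments are NaN (flagged,
    not fabricated); the first segment has no turn angle.
    """
    t = np.asarray(t, dtype=np.int64)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 fixes for kinematics")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValueError(f"non-increasing timestamp at fix index {int(bad[0]) + 1}")
    dist = pairwise_haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    speed = dist / (dt / 3600.0)
    heading = bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    turn = np.full(len(dist), np.nan)
    if len(dist) > 1:
        turn[1:] = _wrap_turn(heading[1:] - heading[:-1])
    return pd.DataFrame({
        "t": t[1:],
        "dt_s": dt,
        "dist_km": dist,
        "speed_kmh": speed,
        "heading_deg": heading,
        "turn_angle_deg": turn,
    })


def straightness(lat, lon) -> float:
    """Straightness index: net displacement / cumulative path length, in [0, 1].

    1 for a perfectly straight path, 0 for a closed loop. A zero-length path
    has undefined straightness and returns NaN (a signal, not a value).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        raise ValueError("need at least 2 fixes for straightness")
    path = float(np.sum(pairwise_haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    if path <= 0.0:
        return float("nan")
    net = float(pairwise_haversine_km(lat[0], lon[0], lat[-1], lon[-1]))
    return min(max(net / path, 0.0), 1.0)


def _unwrap_lon(lon):
    """Unwrap a longitude sequence so consecutive differences are < 180 deg."""
    return np.degrees(np.unwrap(np.radians(np.asarray(lon, dtype=float))))


def interpolate_track(t, lat, lon, tq):
    """Linearly interpolate a track at query times ``tq`` (vectorized).

    Longitudes are unwrapped before interpolation so antimeridian crossings
    interpolate along the short way, then renormalized to [-180, 180).
    Raises on any query time outside [t[0], t[-1]] (no extrapolation).
    """
    t = np.asarray(t, dtype=float)
    tq = np.asarray(tq, dtype=float)
    if len(t) < 1:
        raise ValueError("empty track")
    if np.any(tq < t[0]) or np.any(tq > t[-1]):
        raise ValueError("extrapolation refused: query time outside track span")
    lat_q = np.interp(tq, t, np.asarray(lat, dtype=float))
    lon_q = np.interp(tq, t, _unwrap_lon(lon))
    lon_q = ((lon_q + 180.0) % 360.0) - 180.0
    return lat_q, lon_q


def interpolate_position(t, lat, lon, tq) -> GeoPoint:
    """Track position at a single time ``tq``; exact at the knots."""
    lat_q, lon_q = interpolate_track(t, lat, lon, [tq])
    return GeoPoint(float(lat_q[0]), float(lon_q[0]))
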