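"""Great-circle geometry on WGS84 points.

All distances in this package are great-circle (haversine) distances on a
sphere of radius ``EARTH_RADIUS_KM`` (the IUGG mean Earth radius). At the
5 km buffer scale relevant here, the sphere-vs-ellipsoid error is below
10 m — negligible beside the ~1 km geolocation uncertainty of a MODIS
active-fire pixel — so no ellipsoidal solver or projected CRS is used.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "haversine_km",
    "points_to_arrays",
    "point_to_points_km",
    "pairwise_distance_matrix",
    "medoid",
    "medoid_index",
    "offset_km",
]

EARTH_RADIUS_KM = 6371.0088


class GeoPoint(NamedTuple):
    """A point in decimal degrees WGS84; ``lat`` in [-90, 90], ``lon`` in [-180, 180]."""

    lat: float
    lon: float


def _check_point(p: GeoPoint) -> None:
    if not (-90.0 <= p.lat <= 90.0 and -180.0 <= p.lon <= 180.0):
        raise ValueError(f"coordinates out of range: {p}")


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in km.

    Symmetric, non-negative and zero iff the points coincide.
    """
    a, b = GeoPoint(*a), GeoPoint(*b)
    _check_point(a)
    _check_point(b)
    lat1, lon1, lat2, lon2 = map(np.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def points_to_arrays(points: Sequence[GeoPoint]) -> tuple[np.ndarray, np.ndarray]:
    """Split a point sequence into (lat, lon) float arrays."""
    lats = np.asarray([p[0] for p in points], dtype=float)
    lons = np.asarray([p[1] for p in points], dtype=float)
    return lats, lons


def point_to_points_km(p: GeoPoint, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Distances from one point to arrays of coordinates, vectorised, in km."""
    lat1 = np.radians(p[0])
    lon1 = np.radians(p[1])
    lat2 = np.radians(np.asarray(lats, dtype=float))
    lon2 = np.radians(np.asarray(lons, dtype=float))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def pairwise_distance_matrix(points: Sequence[GeoPoint]) -> np.ndarray:
    """Symmetric n x n matrix of great-circle distances in km, zero diagonal."""
    if len(points) < 1:
        raise ValueError("pairwise_distance_matrix requires at least one point")
    lats, lons = points_to_arrays(points)
    lat = np.radians(lats)[:, None]
    lon = np.radians(lons)[:, None]
    s = (
        np.sin((lat.T - lat) / 2.0) ** 2
        + np.cos(lat) * np.cos(lat.T) * np.sin((lon.T - lon) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def medoid_index(points: Sequence[GeoPoint], d: np.ndarray | None = None) -> int:
    """Index of the member minimising summed distance to all members.

    Ties are broken by the lowest input index, so the result is deterministic.
    """
    if len(points) == 0:
        raise ValueError("medoid of empty point set is undefined")
    if d is None:
        d = pairwise_distance_matrix(points)
    return int(np.argmin(d.sum(axis=1)))  # argmin takes the first minimum


def medoid(points: Sequence[GeoPoint], d: np.ndarray | None = None) -> GeoPoint:
    """The member point minimising summed great-circle distance to all members."""
    p = points[medoid_index(points, d)]
    return GeoPoint(float(p[0]), float(p[1]))


def offset_km(p: GeoPoint, north_km: float = 0.0, east_km: float = 0.0) -> GeoPoint:
    """Displace a point by small north/east offsets (km), local-tangent approximation.

    Used to construct scenes and jittered detections; accurate to well under
    1% for offsets below ~50 km away from the poles.
    """
    dlat = north_km / (EARTH_RADIUS_KM * np.pi / 180.0)
    dlon = east_km / (EARTH_RADIUS_KM * np.pi / 180.0 * np.cos(np.radians(p[0])))
    return GeoPoint(float(p[0] + dlat), float(p[1] + dlon))
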