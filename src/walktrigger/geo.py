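"""Geodesic primitives on the WGS84 sphere.

All distances in this package are great-circle (haversine) distances on a
sphere of mean Earth radius. At the spatial scales of daily mobility
(metres to a few kilometres) the difference from an ellipsoidal geodesic
is far below GPS error, so no projected CRS is used anywhere.
"""
from __future__ import annotations

import math

EARTH_RADIUS_M = 6_371_008.8  # IUGG mean Earth radius


def geodesic_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in metres between two (lat, lon) points in degrees.

    Haversine formula; symmetric, non-negative, zero iff the points coincide.
    """
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    # clamp guards rounding for near-antipodal points
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def destination(lat: float, lon: float, bearing_deg: float, distance_m: float) -> tuple[float, float]:
    """Point reached from (lat, lon) moving `distance_m` along `bearing_deg`.

    Local equirectangular step — adequate for the sub-kilometre steps the
    mobility simulator takes; error is O((d/R)^2).
    """
    theta = math.radians(bearing_deg)
    dlat = distance_m * math.cos(theta) / EARTH_RADIUS_M
    dlon = distance_m * math.sin(theta) / (EARTH_RADIUS_M * math.cos(math.radians(lat)))
    return lat + math.degrees(dlat), lon + math.degrees(dlon)


def path_length_m(points: list[tuple[float, float]]) -> float:
    """Cumulative haversine length of a (lat, lon) polyline."""
    return sum(geodesic_m(points[i], points[i + 1]) for i in range(len(points) - 1))
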