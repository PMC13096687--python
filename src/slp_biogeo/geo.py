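"""Biogeographic coding of regions and genera.

Regions (botanical countries) are classified as tropical when their
latitudinal extent intersects the tropic band, and carry a precomputed
biodiversity-hotspot overlap flag.  A genus is coded tropical / hotspot
when at least a threshold fraction of its occupied regions carry the flag
(ties at the threshold count as state 1).  Distribution centroids come
from the convex hull of the occupied regions' centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Point

__all__ = [
    "CodingConfig",
    "classify_region_tropical",
    "code_genus",
    "genus_centroid",
    "pairwise_geo_distances",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0

#: Latitude of the tropic circles, 23 degrees 27 minutes.
TROPIC_BAND_DEG = 23.45


@dataclass(frozen=True)
class CodingConfig:
    """Thresholds used to code genera from their occupied regions.

    ``occupancy_threshold`` is the minimum fraction of occupied regions
    carrying a flag for the genus to receive state 1 (the study default is
    0.50, with 0.70 as a sensitivity setting for the tropical coding).
    """

    tropic_band: float = TROPIC_BAND_DEG
    occupancy_threshold: float = 0.50

    def __post_init__(self):
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ValueError("occupancy_threshold must be in (0, 1]")
        if self.tropic_band <= 0:
            raise ValueError("tropic_band must be positive")


def classify_region_tropical(lat_extent, config: CodingConfig = CodingConfig()) -> int:
    """1 if ``[min_lat, max_lat]`` intersects the closed tropic band."""
    lo, hi = float(lat_extent[0]), float(lat_extent[1])
    if lo > hi:
        raise ValueError(f"invalid latitudinal extent [{lo}, {hi}]")
    band = config.tropic_band
    return int(hi >= -band and lo <= band)


def code_genus(flags, config: CodingConfig = CodingConfig()) -> int:
    """1 if the mean of the per-region binary flags reaches the threshold."""
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("genus occupies no regions")
    return int(flags.mean() >= config.occupancy_threshold)


def genus_centroid(points) -> tuple[float, float]:
    """Centroid of the convex hull of (lon, lat) points.

    One point maps to itself; two points (and collinear sets, whose hull is
    a segment) map to the midpoint of the extremes; otherwise the area
    centroid of the hull polygon.  Coordinates are treated as planar;
    ranges spanning the antimeridian are not re-wrapped.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) == 0:
        raise ValueError("no points")
    if len(pts) == 1:
        return pts[0]
    hull = MultiPoint(pts).convex_hull  # Point, LineString or Polygon
    c: Point = hull.centroid
    return (float(c.x), float(c.y))


def _haversine_km(lon, lat):
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_geo_distances(points, metric: str = "greatcircle") -> np.ndarray:
    """Symmetric distance matrix between (lon, lat) points.

    ``greatcircle`` uses the haversine formula on a 6371-km sphere (result
    in km); ``euclidean`` works on raw degrees (useful as an oracle).
    Coincident distinct points yield off-diagonal zeros, reported via a
    warning; downstream weighting decides how to handle them.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (lon, lat) points")
    if metric == "greatcircle":
        d = _haversine_km(pts[:, 0], pts[:, 1])
    elif metric == "euclidean":
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(len(pts), dtype=bool)
    n_coincident = int((d[off] == 0.0).sum() // 2)
    if n_coincident:
        warnings.warn(f"{n_coincident} coincident point pair(s) at zero distance")
    return d
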