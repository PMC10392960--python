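"""Geodesic primitives on the WGS84-radius sphere.

All public coordinates are (lon, lat) in decimal degrees; internal work uses
unit vectors on the sphere. Regions are shapely (Multi)Polygons in lon/lat;
point-in-region tests are done in lon/lat space, which assumes the region
does not cross the antimeridian or contain a pole.
"""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def lonlat_to_unit(lon, lat):
    """Convert lon/lat degrees to unit vectors, shape (..., 3)."""
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    cl = np.cos(lat)
    return np.stack([cl * np.cos(lon), cl * np.sin(lon), np.sin(lat)], axis=-1)


def unit_to_lonlat(xyz):
    xyz = np.asarray(xyz, dtype=float)
    lon = np.rad2deg(np.arctan2(xyz[..., 1], xyz[..., 0]))
    lat = np.rad2deg(np.arcsin(np.clip(xyz[..., 2], -1.0, 1.0)))
    return lon, lat


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; broadcasts over array inputs."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def chord_to_arc_km(chord):
    """Euclidean chord length between unit vectors -> great-circle km."""
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))


def _ring_area_sr(lon_deg, lat_deg):
    """Unsigned spherical area (steradians) of a closed ring.

    Chamberlain & Duquette line-integral formula; rings are densified first
    so chord/great-circle discrepancies stay negligible.
    """
    lon = np.asarray(lon_deg, dtype=float)
    lat = np.asarray(lat_deg, dtype=float)
    if lon[0] != lon[-1] or lat[0] != lat[-1]:
        lon = np.append(lon, lon[0])
        lat = np.append(lat, lat[0])
    lam = np.deg2rad(lon)
    phi = np.deg2rad(lat)
    area = np.sum((lam[1:] - lam[:-1]) * (2.0 + np.sin(phi[1:]) + np.sin(phi[:-1])))
    return abs(area) / 2.0


def spherical_area_km2(geom: BaseGeometry, max_seg_deg: float = 0.25) -> float:
    """Area of a lon/lat (Multi)Polygon on the sphere, in km^2."""
    geom = shapely.segmentize(geom, max_seg_deg)
    polys = getattr(geom, "geoms", [geom])
    total = 0.0
    for poly in polys:
        ext = np.asarray(poly.exterior.coords)
        total += _ring_area_sr(ext[:, 0], ext[:, 1])
        for ring in poly.interiors:
            coords = np.asarray(ring.coords)
            total -= _ring_area_sr(coords[:, 0], coords[:, 1])
    return total * EARTH_RADIUS_KM**2


def sample_in_region(region: BaseGeometry, n: int, rng: np.random.Generator):
    """Draw n points uniformly (w.r.t. spherical area) inside region.

    Rejection sampling from the lon/lat bounding box with the sin-latitude
    correction for the sphere. Returns (lon, lat) arrays of length n.
    """
    minx, miny, maxx, maxy = region.bounds
    z_lo, z_hi = np.sin(np.deg2rad([miny, maxy]))
    out_lon = np.empty(0)
    out_lat = np.empty(0)
    # bbox acceptance rate bounded below by area ratio; oversample adaptively
    batch = max(4 * n, 1024)
    while out_lon.size < n:
        lon = rng.uniform(minx, maxx, size=batch)
        lat = np.rad2deg(np.arcsin(rng.uniform(z_lo, z_hi, size=batch)))
        keep = shapely.contains_xy(region, lon, lat)
        out_lon = np.concatenate([out_lon, lon[keep]])
        out_lat = np.concatenate([out_lat, lat[keep]])
        if not keep.any():
            batch *= 2
    return out_lon[:n], out_lat[:n]


def contains_lonlat(region: BaseGeometry, lon, lat):
    return shapely.contains_xy(region, np.asarray(lon, float), np.asarray(lat, float))


class LocalEqualArea:
    """Lambert azimuthal equal-area projection about a reference point.

    Used for planar constructions (convex hulls) at regional scale; output
    coordinates are km east/north of the reference.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._l0 = np.deg2rad(lon0)
        self._p0 = np.deg2rad(lat0)

    def forward(self, lon, lat):
        lam = np.deg2rad(np.asarray(lon, float)) - self._l0
        phi = np.deg2rad(np.asarray(lat, float))
        p0 = self._p0
        denom = 1.0 + np.sin(p0) * np.sin(phi) + np.cos(p0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(np.clip(2.0 / np.clip(denom, 1e-12, None), 0.0, None))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (np.cos(p0) * np.sin(phi) - np.sin(p0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, float) / EARTH_RADIUS_KM
        y = np.asarray(y, float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        p0 = self._p0
        with np.errstate(invalid="ignore"):
            phi = np.where(
                rho > 0,
                np.arcsin(np.clip(np.cos(c) * np.sin(p0) + y * np.sin(c) * np.cos(p0) / np.where(rho > 0, rho, 1.0), -1, 1)),
                p0,
            )
            lam = np.where(
                rho > 0,
                np.arctan2(x * np.sin(c), rho * np.cos(p0) * np.cos(c) - y * np.sin(p0) * np.sin(c)),
                0.0,
            )
        return np.rad2deg(lam + self._l0), np.rad2deg(phi)


def read_region_geojson(path) -> BaseGeometry:
    """Load a Polygon/MultiPolygon (or Feature/FeatureCollection wrapping one)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj["features"]]
        geom = shapely.union_all(geoms)
    elif obj.get("type") == "Feature":
        geom = shape(obj["geometry"])
    else:
        geom = shape(obj)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"region must be Polygon/MultiPolygon, got {geom.geom_type}")
    return geom


def write_geojson(path, features):
    """Write a FeatureCollection; features = iterable of (geometry, properties)."""
    coll = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(coll, fh)
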