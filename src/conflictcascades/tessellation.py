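"""Pseudorandom Voronoi tessellation of a spherical region and temporal binning.

A tessellation at spatial scale ``b`` (km) is an irregular partition of the
region into Voronoi cells of typical radius ``b``: centers are sampled
uniformly in the region, lightly regularized by a few Monte-Carlo Lloyd
iterations, and cells are defined implicitly by great-circle
nearest-center assignment. Irregular cells avoid the directional artifacts
a regular lattice would imprint on the causal network.

Cell adjacency ("touching" cells) is the spherical Delaunay graph of the
centers, obtained as the convex hull of the centers' unit vectors. The
temporal axis is discretized into half-open bins of ``a`` days anchored at
an origin date.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry.base import BaseGeometry

from ._geo import (
    chord_to_arc_km,
    haversine_km,
    lonlat_to_unit,
    sample_in_region,
    spherical_area_km2,
    unit_to_lonlat,
)

# Center count for scale b: n = area / (SPACING_C * b^2), so that the mean
# nearest-neighbor center spacing equals b. For a pure Poisson point process
# the mean spacing is 0.5 * sqrt(area/n) (SPACING_C = 4); two Lloyd
# iterations regularize the pattern and raise the spacing to
# ~0.82 * sqrt(area/n), calibrated once by simulation and fixed here.
SPACING_C = 1.47
N_LLOYD_DEFAULT = 2
_LLOYD_SAMPLES_PER_CELL = 150


@dataclass
class Tessellation:
    """Pseudorandom spherical Voronoi partition of a region at scale ``b``."""

    centers_lon: np.ndarray
    centers_lat: np.ndarray
    region: BaseGeometry
    scale_b: float
    seed: int
    adjacency: list[set[int]]

    @property
    def n_cells(self) -> int:
        return len(self.centers_lon)

    @cached_property
    def _xyz(self) -> np.ndarray:
        return lonlat_to_unit(self.centers_lon, self.centers_lat)

    @cached_property
    def _tree(self) -> cKDTree:
        return cKDTree(self._xyz)

    @cached_property
    def region_area_km2(self) -> float:
        return spherical_area_km2(self.region)

    @cached_property
    def cell_areas_km2(self) -> np.ndarray:
        """Cell areas (km^2) of the region-clipped cells.

        Monte-Carlo: uniform samples in the region are assigned to nearest
        centers; area_i = region_area * fraction_i, so areas sum to the
        region area exactly. Deterministic given the tessellation seed.
        """
        rng = np.random.default_rng([int(self.seed), 0x41E2])
        n_samp = max(50_000, 300 * self.n_cells)
        lon, lat = sample_in_region(self.region, n_samp, rng)
        _, idx = self._tree.query(lonlat_to_unit(lon, lat))
        counts = np.bincount(idx, minlength=self.n_cells)
        return self.region_area_km2 * counts / n_samp

    def assign(self, lon, lat) -> np.ndarray:
        """Nearest-center cell index for each point; -1 outside the region."""
        from ._geo import contains_lonlat

        lon = np.atleast_1d(np.asarray(lon, float))
        lat = np.atleast_1d(np.asarray(lat, float))
        _, idx = self._tree.query(lonlat_to_unit(lon, lat))
        idx = np.atleast_1d(idx).astype(int)
        idx[~contains_lonlat(self.region, lon, lat)] = -1
        return idx

    def mean_nn_spacing_km(self) -> float:
        """Mean great-circle distance from each center to its nearest neighbor."""
        d, _ = self._tree.query(self._xyz, k=2)
        return float(np.mean(chord_to_arc_km(d[:, 1])))

    def adjacency_edges(self) -> list[tuple[int, int]]:
        return sorted({(i, j) for i, nb in enumerate(self.adjacency) for j in nb if i < j})


def _delaunay_adjacency(xyz: np.ndarray) -> list[set[int]]:
    """Spherical Delaunay adjacency = edges of the convex hull of unit vectors."""
    hull = ConvexHull(xyz)
    adj: list[set[int]] = [set() for _ in range(len(xyz))]
    for a, b, c in hull.simplices:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    for i, nb in enumerate(adj):
        nb.discard(i)
    return adj


def build_tessellation(region: BaseGeometry, b_km: float, seed: int,
                       n_lloyd: int = N_LLOYD_DEFAULT) -> Tessellation:
    """Build a pseudorandom Voronoi tessellation with typical cell radius ``b_km``.

    The number of centers is set so the expected nearest-neighbor center
    spacing equals ``b_km``; centers are drawn uniformly in the region then
    relaxed by ``n_lloyd`` Monte-Carlo Lloyd iterations (move each center to
    the spherical centroid of the uniform region samples assigned to it).
    Identical seed gives an identical tessellation.
    """
    if b_km <= 0:
        raise ValueError("b_km must be positive")
    area = spherical_area_km2(region)
    minx, miny, maxx, maxy = region.bounds
    diameter = max(
        haversine_km(minx, miny, maxx, maxy),
        haversine_km(minx, maxy, maxx, miny),
        haversine_km(minx, (miny + maxy) / 2, maxx, (miny + maxy) / 2),
    )
    if b_km > diameter:
        raise ValueError(f"b={b_km} km exceeds the region diameter (~{diameter:.0f} km)")
    n = int(round(area / (SPACING_C * b_km**2)))
    if n < 4:
        raise ValueError(
            f"b={b_km} km gives only {n} cells in this region; need at least 4")

    rng = np.random.default_rng([int(seed), 0x7E55])
    lon, lat = sample_in_region(region, n, rng)
    xyz = lonlat_to_unit(lon, lat)
    if n_lloyd > 0:
        n_samp = min(max(20_000, _LLOYD_SAMPLES_PER_CELL * n), 400_000)
        s_lon, s_lat = sample_in_region(region, n_samp, rng)
        s_xyz = lonlat_to_unit(s_lon, s_lat)
        for _ in range(n_lloyd):
            _, idx = cKDTree(xyz).query(s_xyz)
            sums = np.zeros_like(xyz)
            np.add.at(sums, idx, s_xyz)
            norms = np.linalg.norm(sums, axis=1)
            nonzero = norms > 0
            xyz[nonzero] = sums[nonzero] / norms[nonzero, None]
    lon, lat = unit_to_lonlat(xyz)
    return Tessellation(centers_lon=lon, centers_lat=lat, region=region,
                        scale_b=float(b_km), seed=int(seed),
                        adjacency=_delaunay_adjacency(xyz))


@dataclass
class SpatioTemporalGrid:
    """A tessellation plus half-open temporal bins of ``scale_a`` days.

    Bin ``t`` covers [origin + t*a, origin + (t+1)*a); bins are 0-based.
    """

    tessellation: Tessellation
    origin_date: pd.Timestamp
    scale_a: float
    n_bins: int

    def assign_bins(self, dates) -> np.ndarray:
        """Map dates to bin indices t = floor((date - origin) / a).

        Raises ValueError for dates before the origin or at/after the end
        of the window.
        """
        days = (pd.DatetimeIndex(dates) - self.origin_date) / pd.Timedelta(days=1)
        t = np.floor(np.asarray(days) / self.scale_a).astype(int)
        if len(t) and (t.min() < 0 or t.max() >= self.n_bins):
            raise ValueError("event date outside the study window")
        return t


def make_grid(tess: Tessellation, origin_date, scale_a_days: float,
              end_date=None, n_bins: int | None = None) -> SpatioTemporalGrid:
    """Construct a grid covering [origin_date, end_date] (or n_bins bins)."""
    origin = pd.Timestamp(origin_date)
    if n_bins is None:
        if end_date is None:
            raise ValueError("need end_date or n_bins")
        span = (pd.Timestamp(end_date) - origin) / pd.Timedelta(days=1)
        n_bins = int(np.floor(span / scale_a_days)) + 1
    if n_bins < 1:
        raise ValueError("grid must contain at least one bin")
    return SpatioTemporalGrid(tessellation=tess, origin_date=origin,
                              scale_a=float(scale_a_days), n_bins=int(n_bins))


def grid_for_events(tess: Tessellation, events: pd.DataFrame,
                    scale_a_days: float) -> SpatioTemporalGrid:
    """Grid anchored at the first event date, covering all event dates."""
    if events.empty:
        return make_grid(tess, "2000-01-01", scale_a_days, n_bins=1)
    return make_grid(tess, events["date"].min(), scale_a_days,
                     end_date=events["date"].max())
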