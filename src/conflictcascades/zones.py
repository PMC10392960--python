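"""Probabilistic causal-interaction zones from tessellation ensembles.

The exact avalanche a given event lands in depends on the random Voronoi
tiling. Averaging over an ensemble of tilings turns that sensitivity into
a measure of causal-connection strength: the co-membership probability p
of an event is the fraction of realizations in which it shares an
avalanche with a reference core. Convex hulls of the events at fixed p
levels delimit nested regions of causal interaction — the inner hull is
high-confidence, the outer hull low-confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

from ._geo import LocalEqualArea
from .pipeline import ConflictAvalancheClusterer

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.1, 0.5, 0.9)


@dataclass
class CoMembershipMap:
    """Per-event probability of sharing an avalanche with the reference core."""

    probabilities: pd.Series  # indexed by event_id, values in [0, 1]
    core_event_ids: set[str]
    reference_event: str
    n_realizations: int
    core_quantile: float = 1.0

    def events_at_level(self, level: float) -> pd.Index:
        return self.probabilities.index[self.probabilities >= level]


@dataclass
class ProbabilityHull:
    level: float
    geometry: BaseGeometry  # Polygon, or Point/LineString when degenerate
    n_points: int
    degenerate: bool = False


def avalanche_partitions(events: pd.DataFrame, region, a_days: float, b_km: float,
                         n_realizations: int = 100, master_seed: int = 0,
                         **clusterer_kwargs) -> list[np.ndarray]:
    """Avalanche label arrays (aligned with event rows) over an ensemble of
    tessellation realizations at fixed scales (a, b)."""
    parts = []
    for r in range(n_realizations):
        seed = int(np.random.default_rng([int(master_seed), r]).integers(2**31))
        clus = ConflictAvalancheClusterer(region=region, a_days=a_days, b_km=b_km,
                                          random_state=seed, **clusterer_kwargs)
        parts.append(clus.fit_predict(events))
    return parts


def comembership(events: pd.DataFrame, reference_event: str,
                 realizations: list[np.ndarray],
                 core_quantile: float = 1.0) -> CoMembershipMap:
    """Co-membership probabilities relative to a reference event's core.

    In each realization an event co-occurs if it lies in the same avalanche
    as the reference event; p is the fraction of realizations where it
    does. The core is the set of events co-occurring in at least
    ``core_quantile`` of realizations (1.0 = always, the "central events
    which always appear together").
    """
    ids = events["event_id"].to_numpy()
    where = np.flatnonzero(ids == reference_event)
    if where.size != 1:
        raise ValueError(f"reference event {reference_event!r} not uniquely present")
    ref = int(where[0])
    n = len(realizations)
    if n == 0:
        raise ValueError("need at least one realization")
    co = np.zeros(len(ids))
    for labels in realizations:
        labels = np.asarray(labels)
        if labels.shape[0] != len(ids):
            raise ValueError("realization labels not aligned with events")
        ref_label = labels[ref]
        if ref_label < 0:
            raise ValueError("reference event unassigned in a realization")
        co += (labels == ref_label)
    p = co / n
    probs = pd.Series(p, index=pd.Index(ids, name="event_id"), name="p")
    core = set(ids[p >= core_quantile - 1e-12])
    core.add(reference_event)
    return CoMembershipMap(probabilities=probs, core_event_ids=core,
                           reference_event=reference_event, n_realizations=n,
                           core_quantile=core_quantile)


def probability_hulls(cmap: CoMembershipMap, events: pd.DataFrame,
                      levels=DEFAULT_LEVELS) -> list[ProbabilityHull]:
    """Geodesic convex hulls of the events with p >= level, per level.

    Hulls are computed in a local equal-area projection about the core
    centroid and re-projected to lon/lat; families are nested by
    construction (higher level => subset of points => contained hull).
    Levels with no qualifying events are omitted with a warning; fewer than
    3 non-collinear points give a degenerate (point/segment) hull, flagged.
    """
    by_event = events.set_index("event_id")
    core = by_event.loc[sorted(cmap.core_event_ids)]
    proj = LocalEqualArea(core["lon"].mean(), core["lat"].mean())
    hulls = []
    for level in sorted(levels):
        ids = cmap.events_at_level(level)
        if len(ids) == 0:
            logger.warning("no events at co-membership level %.2f; omitted", level)
            continue
        sub = by_event.loc[ids]
        x, y = proj.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        pts = np.unique(np.column_stack([x, y]), axis=0)
        if len(pts) == 1:
            lon, lat = proj.inverse(pts[:, 0], pts[:, 1])
            geom, degen = Point(lon[0], lat[0]), True
        else:
            try:
                hull = ConvexHull(pts)
                hx, hy = pts[hull.vertices, 0], pts[hull.vertices, 1]
                lon, lat = proj.inverse(hx, hy)
                geom, degen = Polygon(zip(lon, lat)), False
            except Exception:  # collinear points
                lo = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
                lon, lat = proj.inverse(lo[[0, -1], 0], lo[[0, -1], 1])
                geom, degen = LineString(zip(lon, lat)), True
        hulls.append(ProbabilityHull(level=float(level), geometry=geom,
                                     n_points=int(len(ids)), degenerate=degen))
    return hulls
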