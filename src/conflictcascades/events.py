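"""Event-table I/O and synthetic event generation.

The canonical in-memory container is a pandas DataFrame with one row per
event and columns::

    event_id   str
    date       datetime64[ns] (daily resolution)
    lat, lon   WGS84 decimal degrees
    event_type str (lower-cased)
    actors     list[str], non-empty, trimmed and case-folded
    fatalities int >= 0
    geo_precision, time_precision   small int codes

The synthetic generator produces a background Poisson rain of events plus
self-exciting offspring clusters (a spatial Hawkes process with Gaussian
spatial and exponential temporal kernels), with ground-truth parent and
cluster labels so every downstream stage can be tested against a known
causal structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from ._geo import EARTH_RADIUS_KM, contains_lonlat, sample_in_region

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "event_id", "event_date", "latitude", "longitude", "event_type",
    "actor1", "actor2", "fatalities", "geo_precision", "time_precision",
)

KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


class SchemaError(ValueError):
    """Input table is missing a required column."""


class RowParseError(ValueError):
    """A row has an unparseable date or coordinate; carries the row index."""

    def __init__(self, message: str, rows):
        super().__init__(message)
        self.rows = list(rows)


def _normalize_actors(actor1, actor2):
    actors = []
    for a in (actor1, actor2):
        if a is None or (isinstance(a, float) and np.isnan(a)):
            continue
        a = str(a).strip().casefold()
        if a and a not in actors:
            actors.append(a)
    return actors


def read_events(path, type_filter: str | None = None,
                precision_caps: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read and normalize an ACLED-style CSV of point events.

    Parameters
    ----------
    path : str or file-like
        CSV with header row and the required columns.
    type_filter : str, optional
        Keep only events whose ``event_type`` equals this (case-insensitive),
        e.g. ``"battle"`` to restrict to events between armed groups.
    precision_caps : (int, int), optional
        Maximum allowed (geo_precision, time_precision) codes; rows above
        either cap are dropped. Default keeps everything.
    """
    raw = pd.read_csv(path, dtype={"event_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dates = pd.to_datetime(raw["event_date"], errors="coerce", format="mixed", dayfirst=True)
    bad_dates = raw.index[dates.isna()].tolist()
    if bad_dates:
        raise RowParseError(f"unparseable event_date at row(s) {bad_dates[:10]}", bad_dates)
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    lon = pd.to_numeric(raw["longitude"], errors="coerce")
    bad_coord = raw.index[
        lat.isna() | lon.isna() | (lat.abs() > 90) | (lon <= -180) | (lon > 180)
    ].tolist()
    if bad_coord:
        raise RowParseError(f"unparseable/out-of-range coordinates at row(s) {bad_coord[:10]}",
                            bad_coord)

    df = pd.DataFrame({
        "event_id": raw["event_id"].astype(str),
        "date": dates.dt.normalize(),
        "lat": lat.astype(float),
        "lon": lon.astype(float),
        "event_type": raw["event_type"].astype(str).str.strip().str.casefold(),
        "actors": [_normalize_actors(a1, a2)
                   for a1, a2 in zip(raw["actor1"], raw["actor2"])],
        "fatalities": pd.to_numeric(raw["fatalities"], errors="coerce").fillna(0).astype(int).clip(lower=0),
        "geo_precision": pd.to_numeric(raw["geo_precision"], errors="coerce").fillna(1).astype(int),
        "time_precision": pd.to_numeric(raw["time_precision"], errors="coerce").fillna(1).astype(int),
    })

    n0 = len(df)
    if type_filter is not None:
        df = df[df["event_type"] == type_filter.strip().casefold()]
        logger.info("type filter %r dropped %d/%d rows", type_filter, n0 - len(df), n0)
    if precision_caps is not None:
        geo_cap, time_cap = precision_caps
        n1 = len(df)
        df = df[(df["geo_precision"] <= geo_cap) & (df["time_precision"] <= time_cap)]
        logger.info("precision caps %s dropped %d/%d rows", precision_caps, n1 - len(df), n1)
    n2 = len(df)
    df = df[df["actors"].map(len) > 0]
    if len(df) < n2:
        logger.info("dropped %d rows with no named actors", n2 - len(df))
    return df.sort_values("date", kind="stable").reset_index(drop=True)


def write_events(df: pd.DataFrame, path) -> None:
    """Write a normalized event table back to ACLED-style CSV (lossless round trip)."""
    actors = df["actors"].map(list)
    out = pd.DataFrame({
        "event_id": df["event_id"],
        "event_date": df["date"].dt.strftime("%Y-%m-%d"),
        "latitude": df["lat"],
        "longitude": df["lon"],
        "event_type": df["event_type"],
        "actor1": actors.map(lambda a: a[0] if a else ""),
        "actor2": actors.map(lambda a: a[1] if len(a) > 1 else ""),
        "fatalities": df["fatalities"],
        "geo_precision": df["geo_precision"],
        "time_precision": df["time_precision"],
    })
    out.to_csv(path, index=False)


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic event stream.

    ``table`` has one row per event: event_id, parent_id ("" for background
    immigrants), cluster_id (the id of the cluster's root background event).
    ``params`` echoes the generator parameters and seed.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def cluster_sizes(self) -> pd.Series:
        return self.table.groupby("cluster_id").size()


def generate_synthetic_events(
    region: BaseGeometry,
    horizon_days: float,
    background_rate: float = 2e-5,
    branching_ratio: float = 0.5,
    sigma_space_km: float = 50.0,
    sigma_time_days: float = 10.0,
    actor_rule: str = "cluster",
    n_actor_pool: int = 50,
    fatality_exponent: float = 2.5,
    origin_date: str = "1997-01-01",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a subcritical self-exciting (Hawkes) event process in a region.

    Background events arrive as a homogeneous Poisson process with intensity
    ``background_rate`` per km^2 per day over ``region`` x ``horizon_days``.
    Every event independently spawns Poisson(``branching_ratio``) offspring,
    displaced by an isotropic Gaussian of scale ``sigma_space_km`` and delayed
    by an exponential of mean ``sigma_time_days``; offspring falling outside
    the region or beyond the horizon are discarded. ``branching_ratio`` < 1
    keeps clusters finite with mean size 1/(1 - branching_ratio) (before
    boundary losses).

    Actors: with ``actor_rule="cluster"`` each cluster gets its own pair of
    actor names (planted disjoint actor structure); with ``"pool"`` each
    cluster draws its pair from a shared pool of ``n_actor_pool`` names.
    Fatalities are Zipf(``fatality_exponent``) - 1, a heavy-tailed mark.

    Returns the normalized event DataFrame (time-ordered) and the
    :class:`SyntheticTruth` bookkeeping.
    """
    if branching_ratio >= 1:
        raise ValueError("branching_ratio must be < 1 (subcritical)")
    if background_rate <= 0 or sigma_space_km <= 0 or sigma_time_days <= 0:
        raise ValueError("rates and kernel scales must be positive")
    if actor_rule not in ("cluster", "pool"):
        raise ValueError(f"unknown actor_rule {actor_rule!r}")

    from ._geo import spherical_area_km2

    rng = np.random.default_rng(seed)
    area = spherical_area_km2(region)
    n_bg = rng.poisson(background_rate * area * horizon_days)
    lon, lat = sample_in_region(region, n_bg, rng) if n_bg else (np.empty(0), np.empty(0))
    t_bg = rng.uniform(0.0, horizon_days, size=n_bg)

    # breadth-first cascade over generations
    recs = [(float(t), float(lo), float(la), -1, i)
            for i, (t, lo, la) in enumerate(zip(t_bg, lon, lat))]
    frontier = list(range(len(recs)))
    while frontier:
        new_frontier = []
        for idx in frontier:
            t0, lo0, la0, _, cluster = recs[idx]
            for _ in range(rng.poisson(branching_ratio)):
                dt = rng.exponential(sigma_time_days)
                dx, dy = rng.normal(0.0, sigma_space_km, size=2)
                la1 = la0 + dy / KM_PER_DEG
                lo1 = lo0 + dx / (KM_PER_DEG * max(np.cos(np.deg2rad(la0)), 1e-6))
                t1 = t0 + dt
                if t1 >= horizon_days or not contains_lonlat(region, lo1, la1):
                    continue
                recs.append((t1, float(lo1), float(la1), idx, cluster))
                new_frontier.append(len(recs) - 1)
        frontier = new_frontier

    order = np.argsort([r[0] for r in recs], kind="stable")
    pos = {int(old): new for new, old in enumerate(order)}
    ids = [f"SYN{i:06d}" for i in range(len(recs))]

    if actor_rule == "pool":
        pool = [f"actor_{i:03d}" for i in range(n_actor_pool)]
        cluster_actors = {}
    origin = pd.Timestamp(origin_date)
    rows, truth_rows = [], []
    for new, old in enumerate(order):
        t, lo, la, parent, cluster = recs[old]
        if actor_rule == "cluster":
            actors = [f"group_{cluster}a", f"group_{cluster}b"]
        else:
            if cluster not in cluster_actors:
                cluster_actors[cluster] = sorted(rng.choice(len(pool), size=2, replace=False))
            actors = [pool[j] for j in cluster_actors[cluster]]
        rows.append({
            "event_id": ids[new],
            "date": origin + pd.Timedelta(days=int(t)),
            "lat": la, "lon": lo,
            "event_type": "battle",
            "actors": actors,
            "fatalities": int(rng.zipf(fatality_exponent) - 1),
            "geo_precision": 1, "time_precision": 1,
        })
        truth_rows.append({
            "event_id": ids[new],
            "parent_id": ids[pos[parent]] if parent >= 0 else "",
            "cluster_id": f"C{cluster:06d}",
        })
    events = pd.DataFrame(rows, columns=["event_id", "date", "lat", "lon", "event_type",
                                         "actors", "fatalities", "geo_precision",
                                         "time_precision"])
    if events.empty:
        events["date"] = events["date"].astype("datetime64[ns]")
    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows, columns=["event_id", "parent_id", "cluster_id"]),
        params=dict(background_rate=background_rate, branching_ratio=branching_ratio,
                    sigma_space_km=sigma_space_km, sigma_time_days=sigma_time_days,
                    actor_rule=actor_rule, n_actor_pool=n_actor_pool,
                    fatality_exponent=fatality_exponent, horizon_days=horizon_days,
                    origin_date=origin_date, seed=seed, area_km2=area),
    )
    return events, truth
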