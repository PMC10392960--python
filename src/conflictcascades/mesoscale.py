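"""Mesoscale identification: the data-fraction and actor-overlap criteria.

Scanning the separation scales (a, b) changes what the avalanches look
like: at tiny scales activity fragments into singletons, at huge scales
everything fuses into one continent-sized zone. Two first-principles
criteria bracket the useful middle:

* data fraction Phi — the fraction of events belonging to a genuine
  (non-singleton) avalanche must be at least Phi* = 3/4, the midpoint of
  "a majority" (between 1/2 and 1);
* actor overlap Omega — a weighted similarity of actor distributions
  across zones must fall below the midpoint of the attained overlap range
  on a logarithmic axis; big zones that fuse unrelated actors push Omega
  toward 1.

The mesoscale mask marks scale pairs satisfying both, aggregated over an
ensemble of tessellation realizations into a per-scale inclusion
probability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .avalanches import ConflictZone
from .network import DEFAULT_N_SHUFFLES, DEFAULT_P_CUT
from .pipeline import ConflictAvalancheClusterer

logger = logging.getLogger(__name__)

PHI_STAR_DEFAULT = 3 / 4
CONTOUR_LEVELS_DEFAULT = (0.5, 0.9)


def data_fraction(avalanches, events: pd.DataFrame) -> float:
    """Phi: fraction of events that belong to a non-singleton avalanche.

    Singleton avalanches (one active bin) are excluded from the numerator:
    every event trivially sits in some component, so counting singletons
    would make Phi identically 1. The denominator is all events handed to
    the pipeline (events outside the region count against Phi).
    """
    if len(events) == 0:
        raise ValueError("Phi is undefined for zero events")
    in_chain: set[str] = set()
    for av in avalanches:
        if not av.is_singleton:
            in_chain.update(av.event_ids)
    return len(in_chain.intersection(events["event_id"])) / len(events)


def _weighted_overlap(fi: dict[str, float], fj: dict[str, float]) -> float:
    """min-overlap similarity of two actor event-fraction distributions."""
    si, sj = sum(fi.values()), sum(fj.values())
    if si == 0 or sj == 0:
        return 0.0
    common = set(fi) & set(fj)
    num = sum(min(fi[a], fj[a]) for a in common)
    return num / max(si, sj)


def actor_overlap(zones: list[ConflictZone]) -> float:
    """Omega: normalized mean pairwise weighted actor overlap across zones.

    Pairwise overlap w_ij = sum_a min(f_i(a), f_j(a)) / max(|f_i|, |f_j|)
    with f the per-zone actor event-fractions (w_ii = 1). The raw mean W
    over all ordered pairs including self-comparisons is then rescaled as
    Omega = (W - 1/n) / (1 - 1/n), so that zones with pairwise-disjoint
    actors give exactly 0 and identical actor distributions give exactly 1.
    A single zone is maximally self-overlapping: Omega = 1.
    """
    usable = [z for z in zones if z.n_events > 0 and z.actor_distribution]
    if len(usable) < len(zones):
        logger.warning("excluding %d zone(s) with no events from Omega",
                       len(zones) - len(usable))
    n = len(usable)
    if n == 0:
        raise ValueError("Omega needs at least one zone with events")
    if n == 1:
        return 1.0
    total = 0.0
    for zi, zj in itertools.product(usable, repeat=2):
        if zi.zone_id == zj.zone_id:
            total += 1.0
        else:
            total += _weighted_overlap(zi.actor_distribution, zj.actor_distribution)
    w_bar = total / (n * n)
    return (w_bar - 1.0 / n) / (1.0 - 1.0 / n)


def omega_threshold(omegas) -> float:
    """Log-midpoint of the attained positive Omega range.

    The minimally informed cutoff between "fragmented" and "fused" is the
    midpoint of [Omega_min, Omega_max] on a logarithmic axis, i.e. the
    geometric mean of the positive extremes; zeros are excluded from the
    endpoints. Degenerate all-equal input returns that value.
    """
    vals = np.asarray([o for o in np.ravel(np.asarray(list(omegas), dtype=float))
                       if o > 0], dtype=float)
    if vals.size == 0:
        raise ValueError("need positive Omega values for the log-midpoint")
    lo, hi = vals.min(), vals.max()
    if lo == hi and vals.size < 2:
        raise ValueError("need at least two Omega values")
    return float(np.sqrt(lo * hi))


@dataclass
class ScalePoint:
    a: float
    b: float
    phi: float
    omega: float
    n_avalanches: int
    n_zones: int
    seed: int


@dataclass
class MesoscaleMask:
    a_list: list[float]
    b_list: list[float]
    inclusion_probability: np.ndarray  # shape (len(a_list), len(b_list))
    phi_star: float
    omega_stars: dict[int, float]  # per-realization log-midpoint thresholds
    contour_levels: tuple[float, ...] = CONTOUR_LEVELS_DEFAULT

    def peak(self) -> tuple[float, float]:
        """(a, b) with the highest inclusion probability (first on ties)."""
        i, j = np.unravel_index(int(np.argmax(self.inclusion_probability)),
                                self.inclusion_probability.shape)
        return self.a_list[i], self.b_list[j]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"a_days": a, "b_km": b,
             "inclusion_probability": self.inclusion_probability[i, j]}
            for i, a in enumerate(self.a_list) for j, b in enumerate(self.b_list)
        ]
        return pd.DataFrame(rows)


def scan_to_dataframe(points: list[ScalePoint]) -> pd.DataFrame:
    return pd.DataFrame([
        {"a_days": p.a, "b_km": p.b, "seed": p.seed, "phi": p.phi,
         "omega": p.omega, "n_avalanches": p.n_avalanches, "n_zones": p.n_zones}
        for p in points
    ])


def default_a_list() -> list[float]:
    return [float(2**k) for k in range(10)]  # 1..512 days


def default_b_list(n: int = 10) -> list[float]:
    return list(np.geomspace(10.0, 1000.0, n))


def mesoscale_scan(events: pd.DataFrame, region, a_list=None, b_list=None,
                   n_realizations: int = 100, master_seed: int = 0,
                   p_cut: float = DEFAULT_P_CUT,
                   n_shuffles: int = DEFAULT_N_SHUFFLES,
                   phi_star: float = PHI_STAR_DEFAULT,
                   contour_levels=CONTOUR_LEVELS_DEFAULT,
                   ) -> tuple[MesoscaleMask, list[ScalePoint]]:
    """Scan separation scales and delimit the mesoscale.

    For each (a, b) pair and each tessellation realization the full chain
    runs (tessellate, binarize, infer network, build avalanches and zones)
    and Phi and Omega are recorded. Within each realization the Omega
    cutoff is the log-midpoint of that realization's attained positive
    Omega values; a scale pair is in the realization's mask when
    Phi >= phi_star and Omega <= its cutoff. The inclusion probability of a
    scale pair is the fraction of realizations whose mask contains it.

    Scale pairs too coarse for the region (fewer than 4 Voronoi cells) are
    excluded from every mask.
    """
    a_list = list(a_list) if a_list is not None else default_a_list()
    b_list = list(b_list) if b_list is not None else default_b_list()
    points: list[ScalePoint] = []
    shape = (len(a_list), len(b_list))
    masks = np.zeros((n_realizations,) + shape, dtype=bool)
    omega_stars: dict[int, float] = {}

    for r in range(n_realizations):
        seed = int(np.random.default_rng([int(master_seed), r]).integers(2**31))
        grid_vals: dict[tuple[int, int], tuple[float, float]] = {}
        for i, a in enumerate(a_list):
            for j, b in enumerate(b_list):
                try:
                    clus = ConflictAvalancheClusterer(
                        region=region, a_days=a, b_km=b, p_cut=p_cut,
                        n_shuffles=n_shuffles, random_state=seed).fit(events)
                except ValueError as exc:
                    logger.info("scale (a=%g, b=%g) skipped: %s", a, b, exc)
                    continue
                phi = data_fraction(clus.avalanches_, events)
                try:
                    omega = actor_overlap(clus.zones_)
                except ValueError:
                    omega = float("nan")
                points.append(ScalePoint(a=a, b=b, phi=phi, omega=omega,
                                         n_avalanches=len(clus.avalanches_),
                                         n_zones=len(clus.zones_), seed=seed))
                grid_vals[(i, j)] = (phi, omega)
        finite = [om for _, om in grid_vals.values() if np.isfinite(om)]
        try:
            om_star = omega_threshold(finite)
        except ValueError:
            om_star = float("inf")
        omega_stars[seed] = om_star
        for (i, j), (phi, om) in grid_vals.items():
            masks[r, i, j] = (phi >= phi_star) and np.isfinite(om) and (om <= om_star)

    mask = MesoscaleMask(a_list=a_list, b_list=b_list,
                         inclusion_probability=masks.mean(axis=0),
                         phi_star=phi_star, omega_stars=omega_stars,
                         contour_levels=tuple(contour_levels))
    return mask, points
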