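"""Conflict avalanches and conflict zones.

An avalanche is a maximal chain of active spatiotemporal bins linked
through the significant causal network: active (c, t) and (c', t+1) are
linked when c' is adjacent to c and the directed edge c -> c' is
significant; active (c, t) and (c, t+1) are linked when cell c's self-MI
loop is significant. Links are gated by directed edges but components are
taken on the undirected linking graph — a chain is a maximal connected set
of related activity, not a transmission tree. All events in a member
(cell, bin) inherit its avalanche.

Zones merge avalanches whose geographic footprints (cell sets) intersect,
iterated to a fixed point, and carry the distribution of actors over zone
events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .activity import ActivityField
from .network import CausalNetwork
from .tessellation import Tessellation


@dataclass
class Avalanche:
    avalanche_id: int
    active_bins: set[tuple[int, int]]
    event_ids: set[str] = field(default_factory=set)

    @property
    def cells(self) -> set[int]:
        return {c for c, _ in self.active_bins}

    @property
    def start_bin(self) -> int:
        return min(t for _, t in self.active_bins)

    @property
    def end_bin(self) -> int:
        return max(t for _, t in self.active_bins)

    @property
    def is_singleton(self) -> bool:
        """A single active bin: a degenerate avalanche, not a causal chain."""
        return len(self.active_bins) == 1


@dataclass
class ConflictZone:
    zone_id: int
    cells: set[int]
    member_avalanches: set[int]
    actor_distribution: dict[str, float] = field(default_factory=dict)
    n_events: int = 0


def linking_edges(field: ActivityField, network: CausalNetwork) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Explicit list of undirected links between active (cell, bin) pairs."""
    active = field.values
    sig_loops = network.significant_self_loops()
    out_sig: dict[int, list[int]] = {}
    for src, dst in network.significant_edges():
        out_sig.setdefault(src, []).append(dst)
    links = []
    n_bins = field.n_bins
    for c, t in zip(*np.nonzero(active)):
        c, t = int(c), int(t)
        if t + 1 >= n_bins:
            continue
        if c in sig_loops and active[c, t + 1]:
            links.append(((c, t), (c, t + 1)))
        for dst in out_sig.get(c, ()):
            if active[dst, t + 1]:
                links.append(((c, t), (dst, t + 1)))
    return links


def build_avalanches(field: ActivityField, network: CausalNetwork) -> list[Avalanche]:
    """Connected components of active bins under the causal linking rule.

    Every active bin belongs to exactly one avalanche; isolated active bins
    come out as (flagged) singleton avalanches. Avalanches are numbered by
    (start_bin, first cell) for deterministic output.
    """
    if network.graph.number_of_nodes() != field.n_cells:
        raise ValueError("network and activity field disagree on cell count")
    pairs = field.active_pairs()
    pos = {p: i for i, p in enumerate(pairs)}
    links = linking_edges(field, network)
    if links:
        rows = np.array([pos[a] for a, _ in links])
        cols = np.array([pos[b] for _, b in links])
        adj = coo_matrix((np.ones(len(links)), (rows, cols)),
                         shape=(len(pairs), len(pairs)))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(len(pairs))

    comp: dict[int, set[tuple[int, int]]] = {}
    for p, lab in zip(pairs, labels):
        comp.setdefault(int(lab), set()).add(p)
    avalanches = []
    for bins in sorted(comp.values(), key=lambda s: min(s, key=lambda p: (p[1], p[0]))[::-1]):
        evs = set()
        for p in bins:
            evs.update(field.event_index.get(p, ()))
        avalanches.append(Avalanche(avalanche_id=len(avalanches),
                                    active_bins=bins, event_ids=evs))
    return avalanches


def event_labels(avalanches: list[Avalanche], events: pd.DataFrame) -> pd.Series:
    """Avalanche id per event_id (-1 for events in no avalanche, e.g. outside
    the region)."""
    lab = {}
    for av in avalanches:
        for eid in av.event_ids:
            lab[eid] = av.avalanche_id
    return events["event_id"].map(lambda e: lab.get(e, -1)).astype(int)


def actor_fractions(events: pd.DataFrame) -> dict[str, float]:
    """Fraction of events each actor appears in.

    With multi-actor events these need not sum to 1; downstream overlap
    measures must tolerate that.
    """
    n = len(events)
    if n == 0:
        return {}
    counts: Counter[str] = Counter()
    for actors in events["actors"]:
        counts.update(set(actors))
    return {a: c / n for a, c in counts.items()}


def build_conflict_zones(avalanches: list[Avalanche], tess: Tessellation,
                         events: pd.DataFrame | None = None) -> list[ConflictZone]:
    """Merge avalanches with intersecting cell sets into conflict zones.

    Merging is iterated to a fixed point (via union-find over cells), so the
    result is independent of avalanche ordering. Zones partition the
    avalanche-covered cells.
    """
    parent = list(range(len(avalanches)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    owner: dict[int, int] = {}
    for i, av in enumerate(avalanches):
        for c in av.cells:
            if c in owner:
                ri, rj = find(i), find(owner[c])
                if ri != rj:
                    parent[ri] = rj
            else:
                owner[c] = i

    groups: dict[int, set[int]] = {}
    for i in range(len(avalanches)):
        groups.setdefault(find(i), set()).add(i)

    by_event = None
    if events is not None:
        by_event = events.set_index("event_id")
    zones = []
    for members in sorted(groups.values(), key=lambda m: min(m)):
        cells = set().union(*(avalanches[i].cells for i in members))
        evs = set().union(*(avalanches[i].event_ids for i in members))
        dist: dict[str, float] = {}
        if by_event is not None and evs:
            sub = by_event.loc[sorted(evs)]
            dist = actor_fractions(sub.reset_index())
        zones.append(ConflictZone(zone_id=len(zones), cells=cells,
                                  member_avalanches=set(members),
                                  actor_distribution=dist, n_events=len(evs)))
    return zones
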