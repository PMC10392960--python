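"""Directed causal network over touching Voronoi cells.

For every ordered pair of adjacent cells (y -> x) with both activity series
non-constant, transfer entropy is evaluated and tested against the
time-shuffle null; for every cell with a non-constant series, lag-1 self
mutual information is tested the same way. Edges that clear the cutoff
(default p <= 1/20) are the candidate causal connections through which
avalanches may propagate. Restricting candidates to touching cells is the
local-causality assumption: it prunes the hypothesis space and with it a
flood of false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .activity import ActivityField
from .infotheory import shuffle_significance
from .tessellation import Tessellation

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 1 / 20
DEFAULT_N_SHUFFLES = 100


@dataclass
class CausalNetwork:
    """Directed graph on cells with TE edges and self-MI loops.

    ``graph`` is a networkx DiGraph whose edges carry ``measure`` ("te" for
    cross edges, "mi" for self-loops), ``value_bits``, ``exceedance`` and
    ``significant``.
    """

    graph: nx.DiGraph
    p_cut: float
    n_shuffles: int
    seed: int
    n_pairs_tested: int = 0
    n_pairs_skipped: int = 0

    def significant_edges(self) -> set[tuple[int, int]]:
        """Directed (src, dst) cross-cell edges passing the shuffle test."""
        return {(u, v) for u, v, d in self.graph.edges(data=True)
                if u != v and d["significant"]}

    def significant_self_loops(self) -> set[int]:
        """Cells whose lag-1 self-MI passes the shuffle test."""
        return {u for u, v, d in self.graph.edges(data=True)
                if u == v and d["significant"]}

    @property
    def n_significant(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["significant"])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"src_cell": u, "dst_cell": v, "measure": d["measure"],
             "value_bits": d["value_bits"], "exceedance": d["exceedance"],
             "significant": d["significant"], "n_shuffles": self.n_shuffles,
             "p_cut": self.p_cut}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["src_cell", "dst_cell", "measure",
                                           "value_bits", "exceedance", "significant",
                                           "n_shuffles", "p_cut"])


def _pair_rng(seed: int, src: int, dst: int) -> np.random.Generator:
    # independent, order-invariant stream per directed pair
    return np.random.default_rng([int(seed), 0x5EED, int(src) + 1, int(dst) + 1])


def build_causal_network(field: ActivityField, tess: Tessellation,
                         p_cut: float = DEFAULT_P_CUT,
                         n_shuffles: int = DEFAULT_N_SHUFFLES,
                         seed: int = 0) -> CausalNetwork:
    """Infer the significant causal network from a binary activity field.

    Every ordered adjacent pair gets its own RNG stream derived from the
    master seed, so results are reproducible and independent of evaluation
    order. Constant series are skipped (they can carry no lag-1 signal).
    """
    if field.n_cells != tess.n_cells:
        raise ValueError("activity field and tessellation disagree on cell count")
    vals = field.values.astype(np.int8)
    nonconstant = (vals.any(axis=1)) & (~vals.all(axis=1))
    g = nx.DiGraph()
    g.add_nodes_from(range(tess.n_cells))
    tested = skipped = 0

    for c in range(tess.n_cells):
        if not nonconstant[c]:
            continue
        res = shuffle_significance("mi", vals[c], n_shuffles=n_shuffles,
                                   p_cut=p_cut, rng=_pair_rng(seed, c, c))
        g.add_edge(c, c, measure="mi", value_bits=res.value,
                   exceedance=res.exceedance, significant=res.significant)

    for src in range(tess.n_cells):
        for dst in tess.adjacency[src]:
            if not (nonconstant[src] and nonconstant[dst]):
                skipped += 1
                continue
            tested += 1
            res = shuffle_significance("te", vals[dst], vals[src],
                                       n_shuffles=n_shuffles, p_cut=p_cut,
                                       rng=_pair_rng(seed, src, dst))
            g.add_edge(src, dst, measure="te", value_bits=res.value,
                       exceedance=res.exceedance, significant=res.significant)
    if skipped:
        logger.debug("skipped %d adjacent pairs with a constant series", skipped)
    return CausalNetwork(graph=g, p_cut=p_cut, n_shuffles=n_shuffles,
                         seed=int(seed), n_pairs_tested=tested,
                         n_pairs_skipped=skipped)


def null_network(field: ActivityField, tess: Tessellation,
                 mode: str = "time-shuffle",
                 p_cut: float = DEFAULT_P_CUT,
                 n_shuffles: int = DEFAULT_N_SHUFFLES,
                 seed: int = 0) -> CausalNetwork:
    """Causal network inferred on a shuffled field (null model).

    ``"time-shuffle"`` permutes each cell's series independently in time,
    destroying temporal order while preserving per-cell activity totals;
    ``"space-shuffle"`` permutes cell labels, destroying geography.
    A clustered signal should leave only a fragmented residue of edges.
    """
    rng = np.random.default_rng([int(seed), 0x21A11])
    if mode == "time-shuffle":
        shuffled = field.time_shuffled(rng)
    elif mode == "space-shuffle":
        shuffled = field.space_shuffled(rng)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return build_causal_network(shuffled, tess, p_cut=p_cut,
                                n_shuffles=n_shuffles, seed=seed)
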