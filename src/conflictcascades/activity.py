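"""Binary presence/absence activity field over a spatiotemporal grid.

Whether a cell saw one event or a hundred in a time bin, its entry is 1 —
binarization is a deliberate robustness choice: presence/absence is far less
sensitive to reporting errors and magnitude estimation than counts, and it
keeps the state space of the information measures tiny. Fatality and actor
marks stay on the events for downstream modules; they never enter the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .tessellation import SpatioTemporalGrid


@dataclass
class ActivityField:
    """Binary (cell x bin) matrix plus the event ids behind each active entry."""

    values: np.ndarray  # bool, shape (n_cells, n_bins)
    grid: SpatioTemporalGrid
    event_index: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    n_events_outside: int = 0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def series(self, cell: int) -> np.ndarray:
        return self.values[cell]

    def active_pairs(self) -> list[tuple[int, int]]:
        cells, bins = np.nonzero(self.values)
        return list(zip(cells.tolist(), bins.tolist()))

    def to_sparse(self) -> sparse.coo_matrix:
        return sparse.coo_matrix(self.values.astype(np.int8))

    def time_shuffled(self, rng: np.random.Generator) -> "ActivityField":
        """Independently permute each cell's series in time (null model).

        The event index is dropped: shuffled fields exist for network
        inference only.
        """
        vals = self.values.copy()
        for c in range(vals.shape[0]):
            rng.shuffle(vals[c])
        return ActivityField(values=vals, grid=self.grid)

    def space_shuffled(self, rng: np.random.Generator) -> "ActivityField":
        """Permute cell labels (destroys geography, keeps each series intact)."""
        perm = rng.permutation(self.values.shape[0])
        return ActivityField(values=self.values[perm].copy(), grid=self.grid)


def binarize(events: pd.DataFrame, grid: SpatioTemporalGrid) -> ActivityField:
    """Collapse events onto the grid as a binary activity field.

    Events outside the region are dropped (counted in
    ``n_events_outside``); any positive event count in a (cell, bin) yields
    a 1. Idempotent under event duplication.
    """
    tess = grid.tessellation
    values = np.zeros((tess.n_cells, grid.n_bins), dtype=bool)
    index: dict[tuple[int, int], list[str]] = {}
    if events.empty:
        return ActivityField(values=values, grid=grid, event_index=index)
    cells = tess.assign(events["lon"].to_numpy(), events["lat"].to_numpy())
    bins = grid.assign_bins(events["date"])
    inside = cells >= 0
    for eid, c, t in zip(events.loc[inside, "event_id"], cells[inside], bins[inside]):
        values[c, t] = True
        index.setdefault((int(c), int(t)), []).append(eid)
    return ActivityField(values=values, grid=grid, event_index=index,
                         n_events_outside=int((~inside).sum()))


def assign_events(events: pd.DataFrame, grid: SpatioTemporalGrid) -> pd.DataFrame:
    """Return events with ``cell`` (-1 if outside region) and ``bin`` columns."""
    out = events.copy()
    tess = grid.tessellation
    if events.empty:
        out["cell"] = np.array([], dtype=int)
        out["bin"] = np.array([], dtype=int)
        return out
    out["cell"] = tess.assign(events["lon"].to_numpy(), events["lat"].to_numpy())
    out["bin"] = grid.assign_bins(events["date"])
    return out
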