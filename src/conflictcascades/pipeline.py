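"""End-to-end avalanche extraction as a scikit-learn style clusterer.

One realization of the method at fixed separation scales (a, b):
tessellate the region, binarize events onto the grid, infer the
significant causal network, and take connected chains of activity as
avalanches. The estimator follows the sklearn clustering contract:
``fit(events)`` populates fitted attributes and ``labels_`` (one avalanche
id per event row, -1 for events outside the region).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .activity import binarize
from .avalanches import build_avalanches, build_conflict_zones, event_labels
from .network import DEFAULT_N_SHUFFLES, DEFAULT_P_CUT, build_causal_network
from .tessellation import build_tessellation, grid_for_events, make_grid


class ConflictAvalancheClusterer(ClusterMixin, BaseEstimator):
    """Cluster point events into causally linked avalanches at scales (a, b).

    Parameters
    ----------
    region : shapely Polygon/MultiPolygon
        Study region in lon/lat degrees.
    a_days : float, default 64
        Temporal bin duration.
    b_km : float, default 100
        Typical Voronoi cell radius.
    p_cut : float, default 1/20
        Shuffle-test significance cutoff for causal edges.
    n_shuffles : int, default 100
        Permutations per tested pair (must attain ``p_cut``).
    self_links : {"significant", "always"}, default "significant"
        Whether same-cell temporal links require a significant self-MI loop
        (default) or are laid down unconditionally (sensitivity analysis).
    random_state : int, default 0
        Master seed; drives the tessellation and all shuffle streams.

    Attributes (after ``fit``)
    ----------
    tessellation_, grid_, field_, network_ : pipeline stage outputs
    avalanches_ : list of Avalanche
    zones_ : list of ConflictZone
    labels_ : ndarray of avalanche ids aligned with the input rows
    """

    def __init__(self, region=None, a_days: float = 64.0, b_km: float = 100.0,
                 p_cut: float = DEFAULT_P_CUT, n_shuffles: int = DEFAULT_N_SHUFFLES,
                 self_links: str = "significant", random_state: int = 0,
                 origin_date=None, end_date=None):
        self.region = region
        self.a_days = a_days
        self.b_km = b_km
        self.p_cut = p_cut
        self.n_shuffles = n_shuffles
        self.self_links = self_links
        self.random_state = random_state
        self.origin_date = origin_date
        self.end_date = end_date

    def fit(self, X: pd.DataFrame, y=None):
        """Run the full chain on a normalized event table."""
        if self.region is None:
            raise ValueError("region must be provided")
        if self.self_links not in ("significant", "always"):
            raise ValueError(f"unknown self_links mode {self.self_links!r}")
        if not isinstance(X, pd.DataFrame) or "lat" not in X or "date" not in X:
            raise ValueError("X must be a normalized event DataFrame "
                             "(see conflictcascades.events.read_events)")
        events = X.reset_index(drop=True)
        self.tessellation_ = build_tessellation(self.region, self.b_km,
                                                seed=int(self.random_state))
        if self.origin_date is not None:
            end = self.end_date if self.end_date is not None else events["date"].max()
            self.grid_ = make_grid(self.tessellation_, self.origin_date,
                                   self.a_days, end_date=end)
        else:
            self.grid_ = grid_for_events(self.tessellation_, events, self.a_days)
        self.field_ = binarize(events, self.grid_)
        self.network_ = build_causal_network(
            self.field_, self.tessellation_, p_cut=self.p_cut,
            n_shuffles=self.n_shuffles, seed=int(self.random_state))
        if self.self_links == "always":
            g = self.network_.graph
            for c in range(self.tessellation_.n_cells):
                g.add_edge(c, c, measure="mi", value_bits=np.nan,
                           exceedance=0.0, significant=True)
        self.avalanches_ = build_avalanches(self.field_, self.network_)
        self.zones_ = build_conflict_zones(self.avalanches_, self.tessellation_,
                                           events=events)
        self.labels_ = event_labels(self.avalanches_, events).to_numpy()
        self.n_features_in_ = events.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
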