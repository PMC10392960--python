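# conflictcascades

Scale-dependent extraction of causally related chains of point events
("conflict avalanches") from geocoded event data, with uncertainty over the
spatial discretization.

Armed-conflict event datasets (ACLED-style tables: one dated, geolocated,
actor-labeled event per row) record atomic incidents but not how incidents
belong together. `conflictcascades` groups events into causal chains with
an explicitly adjustable resolution: a temporal bin width *a* (days) and a
typical Voronoi cell radius *b* (km). At each scale pair the pipeline

1. partitions the region into a pseudorandom spherical Voronoi tessellation
   at scale *b* and bins time at scale *a*;
2. binarizes activity per (cell, bin) — presence/absence only, which is
   robust to reporting and magnitude errors;
3. infers a directed causal network between touching cells from lag-1
   transfer entropy, and self-influence per cell from lag-1 mutual
   information,

   I[X_t; X_{t+1}] = Σ q(x_t, x_{t+1}) log[ q(x_t, x_{t+1}) / q(x_t)q(x_{t+1}) ],
   T[X; Y] = Σ q(x_t, x_{t+1}, y_t) log[ q(x_{t+1}|x_t, y_t) / q(x_{t+1}|x_t) ],

   keeping only edges that beat a time-shuffle permutation null at
   p ≤ 1/20;
4. grows **avalanches**: maximal chains of active (cell, bin) pairs linked
   through co-occurrence, significant self-loops, and significant directed
   edges to adjacent cells at the next time step; intersecting avalanches
   merge into **conflict zones**;
5. locates the **mesoscale** — the scale pairs where avalanches hold at
   least Φ\* = 3/4 of all events while the weighted actor overlap Ω across
   zones stays below the log-midpoint of its attained range — via an
   ensemble of tessellation realizations;
6. fits power-law tails P(X) ~ X^(−α) above a lower cutoff (MLE with a KS
   scan, bootstrap errors, lognormal likelihood-ratio comparison) to the
   avalanche properties (fatalities, reports, duration, sites, diameter,
   area), fits dynamical scaling X ~ T^(dX/z), and checks the exponent
   relation τ − 1 = (α − 1)/(dX/z);
7. quantifies linkage uncertainty as **co-membership probability** over a
   tessellation ensemble, drawing nested convex hulls at fixed probability
   levels.

A self-exciting (Hawkes) synthetic generator with known parent/cluster
truth makes every stage testable without any external download.

## Worked example

```python
import numpy as np
from shapely.geometry import box
import conflictcascades as cc

region = box(0.0, -4.5, 9.0, 4.5)          # ~1000 x 1000 km, WGS84 degrees
events, truth = cc.generate_synthetic_events(
    region, horizon_days=1460, background_rate=2e-7, branching_ratio=0.8,
    sigma_space_km=40.0, sigma_time_days=15.0, seed=3)

clus = cc.ConflictAvalancheClusterer(region=region, a_days=16, b_km=80,
                                     random_state=1).fit(events)
print(len(events), "events")
print(clus.tessellation_.n_cells, "cells x", clus.grid_.n_bins, "bins")
print(len(clus.network_.significant_edges()), "significant causal edges")
print(len(clus.avalanches_), "avalanches in", len(clus.zones_), "zones")
print("phi =", round(cc.data_fraction(clus.avalanches_, events), 3))
print("omega =", round(cc.actor_overlap(clus.zones_), 3))
```

prints

```
1051 events
106 cells x 92 bins
83 significant causal edges
517 avalanches in 47 zones
phi = 0.511
omega = 0.02
```

Read: of 602 tested ordered neighbor pairs, 83 carry significant directed
transfer entropy; the resulting chains capture 51% of the events
(`phi`) at this scale pair — below the Φ ≥ 3/4 mesoscale criterion, so
(a = 16 d, b = 80 km) is too fine for this stream — and the zones have
almost disjoint actor sets (`omega` ≈ 0.02). `clus.labels_` holds one
avalanche id per event, sklearn-style.

The same pipeline is scriptable from the shell:

```bash
conflictcascades --config run.yaml simulate
conflictcascades --config run.yaml tessellate
conflictcascades --config run.yaml binarize
conflictcascades --config run.yaml network
conflictcascades --config run.yaml avalanches
conflictcascades --config run.yaml mesoscale
conflictcascades --config run.yaml scaling
conflictcascades --config run.yaml zones
```

Each stage writes CSV/GeoJSON artifacts plus a `manifest.json` carrying the
config hash and seeds; identical config and seed reproduce outputs byte for
byte.

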