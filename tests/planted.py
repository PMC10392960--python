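"""Planted two-cluster fixture for co-membership tests.

Two well-separated blob cascades, each a 3x3 grid of sites (70 km apart)
swept by a west-to-east activity wave: a common on/off driver (on-runs 2-4
bins, off-runs exactly 1 bin) reaches each column one bin later, so every
eastward neighbor pair carries deterministic one-step predictive signal
and the avalanche linking graph is redundant. Off-runs are shorter than
the column-delay span, so the wave never goes globally silent and chains
never break in time. An anchor event on day 0 pins the grid origin so the
wave stays phase-locked to the temporal bins.

The planted truth: each cluster should form a single coherent avalanche at
matched scales (a = 16 days, b = 80 km), and the two clusters (600 km
apart) should never join.
"""

import numpy as np
import pandas as pd

CLUSTER_CENTERS = [(2.0, 0.0), (7.4, 0.0)]


def two_cluster_events(seed, a_days=16, n_bins=80, spacing_km=70.0,
                       jitter_km=8.0, horizon=1480.0):
    """Return an event table with a ``cluster`` truth column (-1 = noise)."""
    rng = np.random.default_rng(seed)
    rows = []

    def add(cid, t, lon, lat, actor):
        rows.append(dict(event_id=f"C{cid}_{len(rows):05d}",
                         date=pd.Timestamp("2000-01-01") + pd.Timedelta(days=int(t)),
                         lat=lat, lon=lon, event_type="battle", actors=[actor],
                         fatalities=1, geo_precision=1, time_precision=1,
                         cluster=cid))

    add(-1, 0.0, 4.5, 4.2, "noise")  # grid anchor at day 0
    start_bin = 6
    for cid, (lon0, lat0) in enumerate(CLUSTER_CENTERS):
        D = np.zeros(n_bins, dtype=bool)
        t = 0
        while t < n_bins:
            on = int(rng.integers(2, 5))
            D[t:t + on] = True
            t += on + 1
        for col in range(3):
            for row in range(3):
                slon = lon0 + (col - 1) * spacing_km / 111.2
                slat = lat0 + (row - 1) * spacing_km / 111.2
                for tb in range(n_bins - 3):
                    if not D[max(tb - col, 0)]:
                        continue
                    t0 = (start_bin + tb) * a_days
                    for _ in range(int(rng.integers(3, 6))):
                        dx, dy = rng.normal(0, jitter_km, 2)
                        add(cid, t0 + rng.uniform(0, a_days - 1e-6),
                            slon + dx / 111.2, slat + dy / 111.2, f"g{cid}")
    for _ in range(40):
        add(-1, rng.uniform(1, horizon), rng.uniform(0.2, 8.8),
            rng.uniform(-4.3, 4.3), "noise")
    return pd.DataFrame(rows).sort_values("date").reset_index(drop=True)


def central_reference(events, cid=0):
    """An event near its cluster's spatial center and temporal midpoint."""
    center = CLUSTER_CENTERS[cid]
    sub = events[events.cluster == cid]
    mid = sub["date"].quantile(0.5)
    score = (np.hypot(sub.lon - center[0], sub.lat - center[1]) * 111.2
             + np.abs((sub["date"] - mid).dt.days) / 10.0)
    return sub.loc[score.idxmin(), "event_id"]
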