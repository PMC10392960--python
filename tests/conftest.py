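import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from conflictcascades import generate_synthetic_events


@pytest.fixture(scope="session")
def region():
    """~1000 x 1000 km equatorial box (planar and spherical metrics agree)."""
    return box(0.0, -4.5, 9.0, 4.5)


@pytest.fixture(scope="session")
def clustered_events(region):
    """Moderate self-exciting synthetic stream with known truth."""
    events, truth = generate_synthetic_events(
        region, horizon_days=1460, background_rate=2e-7, branching_ratio=0.8,
        sigma_space_km=40.0, sigma_time_days=15.0, seed=11)
    return events, truth


@pytest.fixture()
def toy_csv(tmp_path):
    """Factory for small ACLED-style CSV files."""

    def make(rows, drop_columns=(), name="toy.csv"):
        df = pd.DataFrame(rows)
        for col in drop_columns:
            df = df.drop(columns=[col])
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return make


@pytest.fixture()
def toy_rows():
    def row(i, etype="battle", date="2001-01-0{}".format, **kw):
        base = dict(event_id=f"E{i}", event_date=f"2001-01-{i + 1:02d}",
                    latitude=1.0 + 0.1 * i, longitude=4.0 + 0.1 * i,
                    event_type=etype, actor1=f"Group {i}", actor2="Militia B",
                    fatalities=i, geo_precision=1, time_precision=1)
        base.update(kw)
        return base

    return [row(0), row(1), row(2), row(3, etype="riot"), row(4, etype="riot")]
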