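"""Shared fixtures: small deterministic telemetry tracks and harvest scenes."""

import numpy as np
import pandas as pd
import pytest
import shapely

from harvestrange.landscape import HarvestLayer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fixes(animal_id, times, xy, collar="GPS", loc_class=None, region="west"):
    """Build a canonical fix frame from parallel time/coordinate sequences."""
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "t": pd.to_datetime(times),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "collar": collar,
            "loc_class": loc_class,
            "region": region,
            "period": None,
        }
    )


@pytest.fixture
def square_block_layers():
    """Single 2 km x 2 km block cut in 2000, plus an older 1990 block."""
    recent = shapely.box(10_000, 10_000, 12_000, 12_000)
    old = shapely.box(30_000, 10_000, 32_000, 12_000)
    return [
        HarvestLayer(year=1990, geometry=old),
        HarvestLayer(year=2000, geometry=recent),
    ]


def summer_track(animal_id, year, center, n=140, spread=1000.0, seed=0,
                 region="west"):
    """Daily summer fixes (May 1 .. Sep 15) scattered around a center."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=year, month=5, day=1, hour=12)
    times = [start + pd.Timedelta(days=i) for i in range(n)]
    xy = np.asarray(center, dtype=float) + rng.normal(0, spread, (n, 2))
    df = make_fixes(animal_id, times, xy, region=region)
    df["season"] = "Summer"
    df["biological_year"] = year
    return df
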