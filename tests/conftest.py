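import numpy as np
import pandas as pd
import pytest

from gomtuna.domain import SpatialDomain, generate_land_mask
from gomtuna.simulate import SimConfig


@pytest.fixture
def domain():
    return SpatialDomain()


@pytest.fixture
def small_domain():
    return SpatialDomain(n_lat=50, n_lon=50)


@pytest.fixture
def coarse_domain():
    return SpatialDomain(n_lat=100, n_lon=100)


@pytest.fixture
def mask(coarse_domain):
    return generate_land_mask(coarse_domain)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_config():
    """One season, one hotspot: quick deterministic inputs."""
    return SimConfig(
        first_year=1997,
        last_year=1997,
        hotspots=((42.5, -69.0, 0.2),),
        drift_rate=0.0,
        n_herring_per_period=20,
        n_schools_per_period=5,
        seed=11,
    )


def make_schools(rows):
    """Schools frame from (date, lat, lon, n_fish) tuples."""
    import datetime as dt

    df = pd.DataFrame(rows, columns=["date", "latitude", "longitude", "n_fish"])
    df["date"] = df["date"].map(lambda d: dt.date.fromisoformat(d) if isinstance(d, str) else d)
    df["year"] = df["date"].map(lambda d: d.year)
    df["day_of_year"] = df["date"].map(lambda d: d.timetuple().tm_yday)
    return df
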