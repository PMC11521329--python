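import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from aerosurv.base import SurveillanceSeries
from aerosurv.synthetic import SyntheticConfig, generate_latent, generate_posts, generate_streams


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Two regions, two years — enough for most stream-level unit tests."""
    return SyntheticConfig(
        n_regions=2,
        n_days=731,
        populations=(800_000, 1_200_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_streams(small_config):
    latent = generate_latent(small_config)
    return generate_streams(latent, small_config)


@pytest.fixture(scope="session")
def small_posts(small_config):
    latent = generate_latent(small_config)
    return generate_posts(latent, small_config)


@pytest.fixture
def toy_regions() -> pd.DataFrame:
    """Two unit squares side by side, one DMA each."""
    return pd.DataFrame(
        {
            "region_id": ["a", "b"],
            "name": ["A", "B"],
            "population": [100_000, 300_000],
            "dma_id": ["d0", "d0"],
            "geometry": [
                Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
                Polygon([(1, 0), (2, 0), (2, 1), (1, 1)]),
            ],
        }
    )


def make_series(
    values, region_id="a", stream="ed_count", start="2016-01-01", smoothed=False
) -> SurveillanceSeries:
    idx = pd.date_range(start, periods=len(values), freq="D")
    return SurveillanceSeries(
        region_id, stream, pd.Series(np.asarray(values, dtype=float), index=idx), smoothed=smoothed
    )
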