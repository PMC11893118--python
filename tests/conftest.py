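import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cropclock import (
    CropRecord,
    SyntheticWeatherParams,
    WeatherSeries,
    simulate_weather,
)


def make_constant_series(
    location_id="const",
    start=dt.date(2021, 1, 1),
    n_days=400,
    tmin=15.0,
    tmax=25.0,
    radiation=20.0,
    vp=18.0,
):
    """A gap-free series with identical weather every day."""
    index = pd.date_range(pd.Timestamp(start), periods=n_days, freq="D")
    frame = pd.DataFrame(
        {
            "tmin": float(tmin),
            "tmax": float(tmax),
            "radiation": float(radiation),
            "vp": float(vp),
        },
        index=index,
    )
    return WeatherSeries(location_id, frame)


@pytest.fixture(scope="session")
def qld_weather():
    """Ten years of seeded synthetic SEQ-style weather."""
    params = SyntheticWeatherParams(seed=42)
    return simulate_weather(params, dt.date(2012, 7, 1), 3650, location_id="gatton")


@pytest.fixture(scope="session")
def weather_map(qld_weather):
    return {"gatton": qld_weather}


@pytest.fixture
def constant_series():
    return make_constant_series()


@pytest.fixture
def sample_crop_records():
    """Crop records matching the synthetic weather coverage."""
    return [
        CropRecord("r1", "gatton", "SEQ", dt.date(2021, 2, 19),
                   dt.date(2021, 4, 1), dt.date(2021, 4, 22), 12092.0),
        CropRecord("r2", "gatton", "SEQ", dt.date(2021, 2, 27),
                   dt.date(2021, 4, 8), dt.date(2021, 4, 28), 10578.0),
        CropRecord("r3", "gatton", "SEQ", dt.date(2020, 10, 15),
                   dt.date(2020, 11, 24), dt.date(2020, 12, 15), 9000.0),
        CropRecord("r4", "gatton", "SEQ", dt.date(2019, 3, 5),
                   dt.date(2019, 4, 14), None, None),
    ]
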