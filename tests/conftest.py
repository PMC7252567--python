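import numpy as np
import pandas as pd
import pytest

from tierexpo.core import Participant, Pollutant, Sex, default_pollutant_params
from tierexpo.microtrac import day_ticks
from tierexpo.octrac import ConcentrationField
from tierexpo.core import Component


@pytest.fixture(scope="session")
def params():
    return default_pollutant_params()


@pytest.fixture
def participant():
    return Participant("P01", 60.0, Sex.MALE, 180.0, 75.0,
                       home_lat=36.00, home_lon=-78.95,
                       work_lat=36.02, work_lon=-78.90)


def make_uniform_field(dates, value=10.0, centroids=None):
    """Field with the same constant value everywhere, all pollutants.

    Background carries 40% of the total, on-road 60%, so additivity is
    nontrivial.
    """
    from tierexpo.synthetic import study_hours

    if centroids is None:
        centroids = [(0, 36.00, -78.95), (1, 36.02, -78.90), (2, 35.95, -79.00)]
    ids = np.array([c[0] for c in centroids])
    lats = np.array([c[1] for c in centroids])
    lons = np.array([c[2] for c in centroids])
    hours = study_hours(dates)
    shape = (len(hours), len(ids))
    values = {}
    for pol in Pollutant:
        values[(pol, Component.BACKGROUND)] = np.full(shape, 0.4 * value)
        values[(pol, Component.ONROAD)] = np.full(shape, 0.6 * value)
        values[(pol, Component.TOTAL)] = np.full(shape, float(value))
    return ConcentrationField(ids, lats, lons, hours, values)


def stationary_track(day, lat, lon, pdop=2.0, valid=True, speed=0.0):
    """A full-day track parked at one point."""
    ticks = day_ticks(day)
    n = len(ticks)
    return pd.DataFrame({
        "timestamp": ticks,
        "lat": np.full(n, lat) if valid else np.full(n, np.nan),
        "lon": np.full(n, lon) if valid else np.full(n, np.nan),
        "speed_kmh": np.full(n, float(speed)),
        "nsat": np.full(n, 8),
        "pdop": np.full(n, float(pdop)),
        "valid": np.full(n, bool(valid)),
    })
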