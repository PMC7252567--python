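from datetime import date

import numpy as np
import pandas as pd
import pytest

from tierexpo.core import Component, Pollutant
from tierexpo.microtrac import PlaceGeometry, day_ticks
from tierexpo.octrac import (ConcentrationField, FieldCoverageError,
                             lag_day_geolocation, nearest_centroid,
                             personal_outdoor_series)
from tierexpo.synthetic import study_hours

from conftest import make_uniform_field, stationary_track

DAY = date(2013, 4, 9)
HOME = (36.00, -78.95)
WORK = (36.02, -78.90)


def chord_nearest(lat, lon, fld):
    """Independent oracle: nearest centroid by 3-D unit-vector chord length."""
    def unit(la, lo):
        la, lo = np.radians(la), np.radians(lo)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo),
                         np.sin(la)])
    q = unit(lat, lon)
    best, best_d = None, np.inf
    for cid, cla, clo in zip(fld.centroid_ids, fld.lats, fld.lons):
        d = np.linalg.norm(unit(cla, clo) - q)
        if d < best_d - 1e-15:
            best, best_d = cid, d
    return best


class TestNearestCentroid:
    def test_query_at_centroid_returns_it(self):
        fld = make_uniform_field([DAY])
        assert nearest_centroid(36.02, -78.90, fld) == 1

    def test_equidistant_tie_breaks_to_lowest_id(self):
        hours = study_hours([DAY])
        values = {(p, c): np.zeros((len(hours), 2)) for p in Pollutant for c in Component}
        fld = ConcentrationField(np.array([5, 9]), np.array([36.0, 36.0]),
                                 np.array([-79.0, -78.9]), hours, values)
        assert nearest_centroid(36.0, -78.95, fld) == 5

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        cents = [(i, 35.85 + 0.25 * rng.random(), -79.1 + 0.35 * rng.random())
                 for i in range(40)]
        fld = make_uniform_field([DAY], centroids=cents)
        for _ in range(200):
            lat = 35.85 + 0.25 * rng.random()
            lon = -79.1 + 0.35 * rng.random()
            assert nearest_centroid(lat, lon, fld) == chord_nearest(lat, lon, fld)


class TestPersonalOutdoorSeries:
    def test_stationary_at_home_matches_home_centroid_series(self):
        fld = make_uniform_field([DAY])
        track = stationary_track(DAY, *HOME, pdop=2.0)
        s = personal_outdoor_series(track, fld, Pollutant.PM25, Component.TOTAL, day=DAY)
        assert len(s) == 17280
        assert (s == 10.0).all()

    def test_uniform_field_is_track_invariant(self):
        fld = make_uniform_field([DAY], value=7.5)
        rng = np.random.default_rng(0)
        track = stationary_track(DAY, *HOME)
        track["lat"] = 35.85 + 0.25 * rng.random(len(track))
        track["lon"] = -79.1 + 0.35 * rng.random(len(track))
        s = personal_outdoor_series(track, fld, Pollutant.CO, Component.TOTAL, day=DAY)
        assert (s == 7.5).all()

    def test_half_day_at_two_centroids_time_weighted_mean(self):
        hours = study_hours([DAY])
        vals = {}
        for p in Pollutant:
            a = np.zeros((len(hours), 2))
            a[:, 0], a[:, 1] = 10.0, 20.0
            vals[(p, Component.BACKGROUND)] = 0.5 * a
            vals[(p, Component.ONROAD)] = 0.5 * a
            vals[(p, Component.TOTAL)] = a
        fld = ConcentrationField(np.array([0, 1]), np.array([36.0, 36.05]),
                                 np.array([-79.0, -78.8]), hours, vals)
        track = stationary_track(DAY, 36.0, -79.0)
        half = len(track) // 2
        track.loc[half:, "lat"] = 36.05
        track.loc[half:, "lon"] = -78.8
        s = personal_outdoor_series(track, fld, Pollutant.EC, Component.TOTAL, day=DAY)
        assert s.mean() == pytest.approx(15.0)

    def test_missing_fix_carries_previous_geolocation(self):
        hours = study_hours([DAY])
        vals = {(p, c): np.tile([5.0, 50.0], (len(hours), 1))
                for p in Pollutant for c in Component}
        for p in Pollutant:
            vals[(p, Component.BACKGROUND)] = 0.5 * vals[(p, Component.TOTAL)]
            vals[(p, Component.ONROAD)] = 0.5 * vals[(p, Component.TOTAL)]
        fld = ConcentrationField(np.array([0, 1]), np.array([36.0, 36.05]),
                                 np.array([-79.0, -78.8]), hours, vals)
        track = stationary_track(DAY, 36.0, -79.0)
        # lose the fix for the second half of the day: values stay at centroid 0
        half = len(track) // 2
        track.loc[half:, ["lat", "lon", "pdop"]] = np.nan
        track.loc[half:, "valid"] = False
        s = personal_outdoor_series(track, fld, Pollutant.NOX, Component.TOTAL, day=DAY)
        assert (s == 5.0).all()

    def test_component_series_add_to_total(self):
        from tierexpo.synthetic import StudyScenario, generate_field
        scenario = StudyScenario(seed=5)
        fld = generate_field(scenario, [DAY])
        track = stationary_track(DAY, 35.95, -78.95)
        for pol in Pollutant:
            bg = personal_outdoor_series(track, fld, pol, Component.BACKGROUND, day=DAY)
            onr = personal_outdoor_series(track, fld, pol, Component.ONROAD, day=DAY)
            tot = personal_outdoor_series(track, fld, pol, Component.TOTAL, day=DAY)
            np.testing.assert_allclose(bg + onr, tot, rtol=1e-12)

    def test_missing_field_hour_raises_coverage_error(self):
        fld = make_uniform_field([DAY])
        track = stationary_track(date(2013, 4, 10), *HOME)
        with pytest.raises(FieldCoverageError):
            personal_outdoor_series(track, fld, Pollutant.PM25, Component.TOTAL,
                                    day=date(2013, 4, 10))


class TestLagDayGeolocation:
    @pytest.fixture
    def places(self):
        return PlaceGeometry(home_lat=HOME[0], home_lon=HOME[1],
                             work_lat=WORK[0], work_lon=WORK[1])

    def test_weekday_lag_keeps_geolocations(self, places):
        track = stationary_track(DAY, *WORK)
        lag = lag_day_geolocation(track, date(2013, 4, 5), False, places)
        assert (lag["lat"] == track["lat"]).all()
        assert lag["timestamp"].iloc[0].date() == date(2013, 4, 5)

    def test_weekend_lag_relocates_work_samples_home(self, places):
        track = stationary_track(DAY, *WORK)
        lag = lag_day_geolocation(track, date(2013, 4, 6), True, places)
        assert (lag["lat"] == HOME[0]).all()
        assert (lag["lon"] == HOME[1]).all()

    def test_no_work_location_unchanged(self):
        places = PlaceGeometry(home_lat=HOME[0], home_lon=HOME[1])
        track = stationary_track(DAY, *WORK)
        lag = lag_day_geolocation(track, date(2013, 4, 6), True, places)
        assert (lag["lat"] == WORK[0]).all()
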