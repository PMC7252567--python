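from datetime import date

import numpy as np
import pytest

from tierexpo.core import Component, Pollutant
from tierexpo.microtrac import ME7, PlaceGeometry, haversine_m
from tierexpo.synthetic import (StudyScenario, generate_clinic_days,
                                generate_cohort, generate_field,
                                generate_participant_day, generate_weather,
                                schedule_study)

DAY = date(2013, 4, 9)


@pytest.fixture(scope="module")
def scenario():
    return StudyScenario(seed=11)


@pytest.fixture(scope="module")
def fld(scenario):
    return generate_field(scenario, [DAY])


class TestField:
    def test_total_is_background_plus_onroad(self, fld):
        for pol in Pollutant:
            np.testing.assert_array_equal(
                fld.values[(pol, Component.TOTAL)],
                fld.values[(pol, Component.BACKGROUND)]
                + fld.values[(pol, Component.ONROAD)])

    def test_concentrations_nonnegative(self, fld):
        for arr in fld.values.values():
            assert (arr >= 0).all()

    def test_onroad_decays_with_road_distance(self, scenario, fld):
        onr = fld.values[(Pollutant.EC, Component.ONROAD)].mean(axis=0)
        from tierexpo.synthetic import _road_distance_m
        dists = np.min(_road_distance_m(scenario, fld.lats, fld.lons), axis=0)
        order = np.argsort(dists)
        # monotone trend: nearest decile well above farthest decile
        k = max(1, len(order) // 10)
        assert onr[order[:k]].mean() > 5 * onr[order[-k:]].mean()

    def test_near_road_gradients_strongest_for_ec_nox(self, scenario, fld):
        """On-road share exceeds background near roads for EC and NOx only."""
        from tierexpo.synthetic import _road_distance_m
        dists = np.min(_road_distance_m(scenario, fld.lats, fld.lons), axis=0)
        near = dists < 200.0
        assert near.any()
        share = {}
        for pol in Pollutant:
            onr = fld.values[(pol, Component.ONROAD)][:, near].mean()
            bg = fld.values[(pol, Component.BACKGROUND)][:, near].mean()
            share[pol] = onr / bg
        assert share[Pollutant.EC] > 1.0
        assert share[Pollutant.NOX] > 1.0
        assert share[Pollutant.PM25] < 1.0
        assert share[Pollutant.CO] < 1.0

    def test_same_seed_bit_identical(self, scenario, fld):
        again = generate_field(StudyScenario(seed=11), [DAY])
        for key in fld.values:
            np.testing.assert_array_equal(fld.values[key], again.values[key])

    def test_different_seed_differs(self, fld):
        other = generate_field(StudyScenario(seed=12), [DAY])
        assert not np.array_equal(other.values[(Pollutant.PM25, Component.TOTAL)],
                                  fld.values[(Pollutant.PM25, Component.TOTAL)])


class TestWeather:
    def test_covers_window_and_is_physical(self, scenario):
        wx = generate_weather(scenario, [DAY])
        assert len(wx) == 24
        assert (wx["wind_mps"] >= 0).all()
        assert wx["t_out_c"].between(-25, 45).all()


@pytest.fixture(scope="module")
def places():
    return PlaceGeometry(home_lat=36.0, home_lon=-78.95,
                         work_lat=36.05, work_lon=-78.85)


class TestParticipantDay:
    def test_reproducible_from_seed(self, scenario, places):
        a = generate_participant_day(scenario, places, 0, DAY)
        b = generate_participant_day(scenario, places, 0, DAY)
        assert a[0].equals(b[0])
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_array_equal(a[3].codes, b[3].codes)

    def test_counts_are_nonnegative_integers(self, scenario, places):
        _, counts, _, _ = generate_participant_day(scenario, places, 0, DAY)
        assert counts.dtype.kind == "i"
        assert counts.size == 86400
        assert (counts >= 0).all()

    def test_home_truth_ticks_are_near_home(self, scenario, places):
        track, _, _, truth = generate_participant_day(scenario, places, 0, DAY)
        home_ticks = (truth.codes == ME7.IN_HOME) & track["valid"].to_numpy()
        d = haversine_m(track.loc[home_ticks, "lat"], track.loc[home_ticks, "lon"],
                        places.home_lat, places.home_lon)
        assert np.nanmax(d) < places.home_radius_m

    def test_vehicle_truth_ticks_exceed_speed_threshold(self, scenario, places):
        track, _, _, truth = generate_participant_day(scenario, places, 0, DAY)
        veh = (truth.codes == ME7.IN_VEHICLE) & track["valid"].to_numpy()
        assert veh.any()
        assert (track.loc[veh, "speed_kmh"] > places.vehicle_speed_kmh).all()

    def test_weekend_plan_has_no_work(self, scenario, places):
        _, _, _, truth = generate_participant_day(scenario, places, 0,
                                                  date(2013, 4, 13))
        assert not np.isin(truth.codes, [ME7.IN_WORK, ME7.OUT_WORK]).any()


class TestSchedule:
    def test_panel_scale_schedule_arithmetic(self):
        scenario = StudyScenario(seed=1)
        clinic = generate_clinic_days(scenario)
        assert len(clinic) == 120
        sched = schedule_study(clinic, scenario.n_lags)
        assert len(sched) == 720

    def test_clinic_days_are_weekdays(self):
        clinic = generate_clinic_days(StudyScenario(seed=2))
        assert all(d.weekday() < 5 for _, d in clinic)

    def test_lag_days_precede_clinic_day(self):
        sched = schedule_study([("P01", DAY)], 5)
        deltas = [(s.clinic_date - s.date).days for s in sched]
        assert sorted(deltas) == [0, 1, 2, 3, 4, 5]


class TestCohort:
    def test_cohort_size_and_validity(self, scenario):
        cohort = generate_cohort(scenario)
        assert len(cohort) == scenario.n_participants
        for pid, (p, h, g) in cohort.items():
            assert p.age >= 18
            assert h.volume_m3 > 0
            assert g.home_lat == p.home_lat
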