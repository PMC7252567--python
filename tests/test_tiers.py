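from datetime import date

import numpy as np
import pandas as pd
import pytest

from tierexpo.aer import QuestionnaireDay
from tierexpo.core import Component, Pollutant
from tierexpo.microtrac import ME7, MicroenvSeries, day_ticks
from tierexpo.synthetic import (StudyScenario, generate_study, schedule_study)
from tierexpo.tiers import (AT_MIN, ScheduledDay, daily_metrics, dose_tick,
                            exposure_tick, records_to_frame, run_study)
from tierexpo.vtrac import default_nmv_table

from conftest import make_uniform_field, stationary_track

DAY = date(2013, 4, 9)


def onehot5(cls):
    v = np.zeros(5, dtype=int)
    v[cls] = 1
    return v


class TestExposureTick:
    def test_outdoors_factor_is_one(self, params):
        e = exposure_tick(onehot5(4), 3.0, 10.0, params[Pollutant.PM25])
        assert e == 10.0

    def test_in_home_uses_indoor_concentration(self, params):
        e = exposure_tick(onehot5(0), 3.0, 10.0, params[Pollutant.PM25])
        assert e == 3.0

    def test_vehicle_infiltration_pm25(self, params):
        e = exposure_tick(onehot5(3), 0.0, 1.0, params[Pollutant.PM25])
        assert e == pytest.approx(0.44)

    def test_work_infiltration_ec(self, params):
        e = exposure_tick(onehot5(1), 0.0, 1.0, params[Pollutant.EC])
        assert e == pytest.approx(0.59)

    def test_other_building_same_factor_as_work(self, params):
        for pol in Pollutant:
            p = params[pol]
            assert exposure_tick(onehot5(2), 0.0, 1.0, p) \
                == exposure_tick(onehot5(1), 0.0, 1.0, p)

    def test_non_one_hot_rejected(self, params):
        with pytest.raises(ValueError, match="one-hot"):
            exposure_tick(np.array([1, 1, 0, 0, 0]), 1.0, 1.0, params[Pollutant.CO])


class TestDoseTick:
    def test_direct_evaluation(self):
        d = dose_tick(np.array([10.0]), 0.012, 2.0)
        assert d[0] == pytest.approx(10.0 * 0.012 * (5 / 60) / 2.0)
        assert d[0] == pytest.approx(0.005)

    def test_zero_mv_zero_dose(self):
        assert (dose_tick(np.ones(7), 0.0, 1.9) == 0).all()

    def test_inverse_in_bsa(self):
        e = np.array([4.0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(dose_tick(e, 0.01, 2.0) * 2,
                                   dose_tick(e, 0.01, 1.0))

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(ValueError):
            dose_tick(np.ones(7), 0.01, 0.0)

    def test_at_is_exact_five_sixtieths(self):
        assert AT_MIN == 5 / 60


def _home_all_day_inputs(value=12.0):
    ticks = day_ticks(DAY)
    me7 = MicroenvSeries(ticks, np.full(17280, ME7.IN_HOME, dtype=np.int8))
    hours = pd.date_range(pd.Timestamp(DAY) + pd.Timedelta(hours=8), periods=24,
                          freq="h")
    c_out_home = pd.Series(np.full(24, value), index=hours)
    c_in = pd.Series(np.full(24, 0.6 * value), index=hours)
    c_out_pers = pd.Series(np.full(17280, value), index=ticks)
    mv = np.full(17280, 0.012)
    return me7, c_out_home, c_in, c_out_pers, mv


class TestDailyMetrics:
    def test_home_all_day_tier4_equals_tier2(self, participant, params):
        me7, c_out_home, c_in, c_out_pers, mv = _home_all_day_inputs()
        rec = daily_metrics(participant, DAY, Pollutant.PM25, Component.TOTAL,
                            me7, c_out_home, c_in, c_out_pers, mv,
                            params[Pollutant.PM25])
        assert rec.tier4_exposure == pytest.approx(rec.tier2_c_in_home, rel=1e-12)
        assert rec.tier3_c_out_personal == pytest.approx(rec.tier1_c_out_home)

    def test_dose_and_time_concentrate_in_home(self, participant, params):
        me7, c_out_home, c_in, c_out_pers, mv = _home_all_day_inputs()
        rec = daily_metrics(participant, DAY, Pollutant.PM25, Component.TOTAL,
                            me7, c_out_home, c_in, c_out_pers, mv,
                            params[Pollutant.PM25])
        assert rec.time_by_me[ME7.IN_HOME] == 1440.0
        assert rec.dose_by_me[ME7.IN_HOME] == pytest.approx(rec.tier5_dose_total)
        assert (rec.dose_by_me[1:] == 0).all()
        # hand check: E=7.2 steady, MV=0.012, AT=5/60, BSA from participant
        expected = 17280 * 7.2 * 0.012 * (5 / 60) / participant.body_surface_area_m2
        assert rec.tier5_dose_total == pytest.approx(expected, rel=1e-9)

    def test_conservation_invariants_enforced(self, participant, params):
        me7, c_out_home, c_in, c_out_pers, mv = _home_all_day_inputs()
        rec = daily_metrics(participant, DAY, Pollutant.EC, Component.TOTAL,
                            me7, c_out_home, c_in, c_out_pers, mv,
                            params[Pollutant.EC])
        assert np.sum(rec.time_by_me) == pytest.approx(1440.0)
        assert np.sum(rec.dose_by_me) == pytest.approx(rec.tier5_dose_total,
                                                       rel=1e-12)

    def test_short_series_rejected(self, participant, params):
        me7, c_out_home, c_in, c_out_pers, mv = _home_all_day_inputs()
        with pytest.raises(ValueError, match="24-h window"):
            daily_metrics(participant, DAY, Pollutant.EC, Component.TOTAL,
                          me7, c_out_home.iloc[:20], c_in, c_out_pers, mv,
                          params[Pollutant.EC])


@pytest.fixture(scope="module")
def small_study():
    scenario = StudyScenario(seed=9, n_participants=1,
                             visit_weeks_per_participant=1,
                             clinic_days_per_visit=1)
    return generate_study(scenario)


class TestRunStudy:
    def test_one_clinic_day_yields_72_records(self, small_study):
        s = small_study
        recs = run_study(s.cohort, s.fields, s.weather, s.questionnaires,
                         s.tracks, s.accel, s.schedule, default_nmv_table())
        assert len(s.schedule) == 6
        assert len(recs) == 6 * 4 * 3

    def test_lag_records_marked_imputed(self, small_study):
        s = small_study
        recs = run_study(s.cohort, s.fields, s.weather, s.questionnaires,
                         s.tracks, s.accel, s.schedule, default_nmv_table())
        df = records_to_frame(recs)
        clinic = s.clinic_days[0][1]
        assert (~df[df["date"] == clinic]["imputed"]).all()
        assert df[df["date"] != clinic]["imputed"].all()

    def test_empty_schedule_empty_output(self, small_study):
        s = small_study
        recs = run_study(s.cohort, s.fields, s.weather, s.questionnaires,
                         s.tracks, s.accel, [], default_nmv_table())
        assert recs == []

    def test_co_constant_field_tier4_equals_tier1(self, participant, params):
        """No indoor or in-vehicle attenuation of CO: with a spatially and
        temporally constant field every tier concentration coincides."""
        fld = make_uniform_field([DAY], value=400.0)
        places_home = (participant.home_lat, participant.home_lon)
        track = stationary_track(DAY, *places_home, pdop=8.0)
        from tierexpo.microtrac import PlaceGeometry
        cohort = {participant.id: (participant,
                                   _simple_home(), PlaceGeometry(
                                       home_lat=places_home[0],
                                       home_lon=places_home[1]))}
        hours = fld.hours
        weather = pd.DataFrame({"t_out_c": 10.0, "wind_mps": 2.0}, index=hours)
        quest = QuestionnaireDay(DAY, 21.0, False, False, False)
        schedule = [ScheduledDay(participant.id, DAY, DAY)]
        recs = run_study(cohort, {DAY: fld}, weather,
                         {(participant.id, DAY): quest},
                         {(participant.id, DAY): track},
                         {(participant.id, DAY): np.zeros(86400, dtype=int)},
                         schedule, default_nmv_table())
        df = records_to_frame(recs)
        co = df[(df["pollutant"] == "CO") & (df["component"] == "total")].iloc[0]
        assert co["tier4"] == pytest.approx(co["tier1"], rel=1e-6)
        assert co["tier2"] == pytest.approx(co["tier1"], rel=1e-6)


def _simple_home():
    from tierexpo.aer import HomeModel
    return HomeModel(id="H1", a_leak_m2=0.05, volume_m3=300.0)


class TestScheduleArithmetic:
    def test_one_clinic_day_gives_six(self):
        sched = schedule_study([("P01", DAY)], n_lags=5)
        assert len(sched) == 6
        assert sched[-1].is_clinic_day
        assert [s.date for s in sched] == sorted(s.date for s in sched)

    def test_zero_clinic_days(self):
        assert schedule_study([], 5) == []
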