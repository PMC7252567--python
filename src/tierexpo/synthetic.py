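"""Synthetic study generator: a complete panel study the pipeline can run.

Generates everything the exposure model consumes, with ground truth kept
alongside the observations:

* an hourly concentration field (background + on-road + total) on a
  centroid grid, with smooth diurnal/synoptic background and sharp
  distance-decay plumes around road polylines — strongest for EC and
  NOx, so near-road gradients dominate those pollutants;
* hourly weather (outdoor temperature, wind);
* a cohort of adult participants with homes, building characteristics
  and (for most) workplaces;
* a clinic-day schedule (two consecutive weekdays per visit week) and
  the five lag days preceding each clinic day;
* per clinic day: a 5-s GPS track realized from a ground-truth
  microenvironment day-plan (with indoor fix degradation), a 1-s
  accelerometer count series driven by the planned activity level, and
  a daily questionnaire.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .aer import HomeModel, QuestionnaireDay
from .core import (DAY_START_HOUR, TICKS_PER_DAY, TICK_SECONDS, Component,
                   Participant, Pollutant, Sex)
from .microtrac import ME7, MicroenvSeries, PlaceGeometry, day_ticks
from .octrac import ConcentrationField
from .tiers import ScheduledDay
from .vtrac import PalLevel

# stream ids for derived RNGs
_S_SPATIAL, _S_DAYFAC, _S_WEATHER, _S_COHORT, _S_DAY, _S_QUEST, _S_SCHED = range(1, 8)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(k) for k in keys]))


@dataclass(frozen=True)
class RoadSpec:
    """A road polyline (WGS84 vertices) with per-pollutant peak strengths."""

    points: Tuple[Tuple[float, float], ...]  # (lat, lon)
    peak_ugm3: Mapping[Pollutant, float]


def _default_roads() -> Tuple[RoadSpec, ...]:
    # peak near-road contributions: EC and NOx exceed their background
    # means near the road; PM2.5 and CO stay background-dominated
    peaks = {Pollutant.PM25: 3.0, Pollutant.EC: 2.5,
             Pollutant.NOX: 80.0, Pollutant.CO: 120.0}
    highway = RoadSpec(points=((35.86, -79.09), (35.98, -78.95), (36.09, -78.78)),
                       peak_ugm3=peaks)
    arterial = RoadSpec(points=((36.09, -79.02), (35.95, -78.99), (35.86, -78.93)),
                        peak_ugm3={p: 0.5 * v for p, v in peaks.items()})
    return (highway, arterial)


@dataclass(frozen=True)
class StudyScenario:
    """Parameters of the synthetic study; defaults mirror the panel design.

    15 adult participants, 8 clinic days each (two consecutive weekdays
    in each of four visit weeks) spread over roughly 25 months, five lag
    days per clinic day, a three-county-scale domain with a centroid
    grid, and two emitting roads.
    """

    seed: int = 0
    n_participants: int = 15
    visit_weeks_per_participant: int = 4
    clinic_days_per_visit: int = 2
    n_lags: int = 5
    start_date: Date = Date(2012, 5, 1)
    n_weeks: int = 108
    lat_min: float = 35.85
    lat_max: float = 36.10
    lon_min: float = -79.10
    lon_max: float = -78.75
    grid_spacing_deg: float = 0.03
    roads: Tuple[RoadSpec, ...] = field(default_factory=_default_roads)
    background_mean: Mapping[Pollutant, float] = field(default_factory=lambda: {
        Pollutant.PM25: 10.0, Pollutant.EC: 0.5,
        Pollutant.NOX: 20.0, Pollutant.CO: 300.0})
    background_diurnal_amp: float = 0.25
    background_day_sigma: float = 0.25
    spatial_sigma: float = 0.12
    onroad_decay_m: float = 250.0
    # GPS realization
    indoor_fix_prob: float = 0.5
    indoor_pdop_logmean: float = math.log(6.0)
    indoor_pdop_logsd: float = 0.35
    outdoor_fix_prob: float = 0.98
    outdoor_pdop_logmean: float = math.log(2.0)
    outdoor_pdop_logsd: float = 0.25
    vehicle_fix_prob: float = 0.95
    position_noise_m: float = 6.0
    drive_speed_kmh: float = 45.0
    # accelerometer mean counts per second by PAL
    counts_per_s: Mapping[int, float] = field(default_factory=lambda: {
        int(PalLevel.SEDENTARY): 0.8, int(PalLevel.LIGHT): 8.0,
        int(PalLevel.MODERATE): 40.0, int(PalLevel.VIGOROUS): 80.0})

    @property
    def clinic_days_per_participant(self) -> int:
        return self.visit_weeks_per_participant * self.clinic_days_per_visit

    def centroid_grid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        lats = np.arange(self.lat_min, self.lat_max + 1e-9, self.grid_spacing_deg)
        lons = np.arange(self.lon_min, self.lon_max + 1e-9, self.grid_spacing_deg)
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        ids = np.arange(glat.size)
        return ids, glat.ravel(), glon.ravel()


# local equirectangular projection for road distances (county scale)
def _project_m(lat, lon, lat0: float, lon0: float):
    x = (np.asarray(lon) - lon0) * 111_320.0 * math.cos(math.radians(lat0))
    y = (np.asarray(lat) - lat0) * 110_540.0
    return x, y


def _road_distance_m(scenario: StudyScenario, lats: np.ndarray,
                     lons: np.ndarray) -> List[np.ndarray]:
    """Distance (m) from each point to each road polyline."""
    lat0 = 0.5 * (scenario.lat_min + scenario.lat_max)
    lon0 = 0.5 * (scenario.lon_min + scenario.lon_max)
    xs, ys = _project_m(lats, lons, lat0, lon0)
    out = []
    for road in scenario.roads:
        rx, ry = _project_m(np.array([p[0] for p in road.points]),
                            np.array([p[1] for p in road.points]), lat0, lon0)
        line = LineString(np.column_stack([rx, ry]))
        out.append(np.array([line.distance(Point(x, y)) for x, y in zip(xs, ys)]))
    return out


def _spatial_surface(scenario: StudyScenario, pollutant: Pollutant,
                     lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Smooth multiplicative spatial factor around 1 for the background."""
    from scipy.interpolate import RegularGridInterpolator

    rng = _rng(scenario.seed, _S_SPATIAL, list(Pollutant).index(pollutant))
    n = 5
    coarse_lat = np.linspace(scenario.lat_min, scenario.lat_max, n)
    coarse_lon = np.linspace(scenario.lon_min, scenario.lon_max, n)
    coarse = rng.normal(1.0, scenario.spatial_sigma, size=(n, n))
    interp = RegularGridInterpolator((coarse_lat, coarse_lon), coarse,
                                     method="linear", bounds_error=False,
                                     fill_value=None)
    return np.clip(interp(np.column_stack([lats, lons])), 0.2, None)


def _diurnal_background(hod: np.ndarray, amp: float) -> np.ndarray:
    return 1.0 + amp * np.sin(2.0 * np.pi * (hod - 9.0) / 24.0)


def _diurnal_traffic(hod: np.ndarray) -> np.ndarray:
    morning = np.exp(-0.5 * ((hod - 8.0) / 1.8) ** 2)
    evening = np.exp(-0.5 * ((hod - 17.5) / 2.2) ** 2)
    return 0.25 + 0.75 * (morning + evening)


def study_hours(dates: Sequence[Date],
                day_start_hour: int = DAY_START_HOUR) -> pd.DatetimeIndex:
    """Union of the 24-h hourly windows of the given dates, sorted unique."""
    parts = [pd.date_range(pd.Timestamp(d) + pd.Timedelta(hours=day_start_hour),
                           periods=24, freq="h") for d in sorted(set(dates))]
    return pd.DatetimeIndex(np.unique(np.concatenate([p.asi8 for p in parts]))
                            .astype("datetime64[ns]"))


def generate_field(scenario: StudyScenario, dates: Sequence[Date],
                   day_start_hour: int = DAY_START_HOUR) -> ConcentrationField:
    """Hourly background/on-road/total concentrations on the centroid grid."""
    ids, lats, lons = scenario.centroid_grid()
    hours = study_hours(dates, day_start_hour)
    hod = (hours.hour + hours.minute / 60.0).to_numpy()
    day_ord = np.array([ts.date().toordinal() for ts in hours])

    uniq_days = np.unique(day_ord)
    bg_dayfac = {}
    onr_dayfac = {}
    for d in uniq_days:
        rng = _rng(scenario.seed, _S_DAYFAC, int(d))
        bg_dayfac[d] = np.exp(rng.normal(0.0, scenario.background_day_sigma, len(Pollutant)))
        onr_dayfac[d] = np.exp(rng.normal(0.0, scenario.background_day_sigma, len(Pollutant)))
    bg_day = np.array([bg_dayfac[d] for d in day_ord])   # (n_hours, 4)
    onr_day = np.array([onr_dayfac[d] for d in day_ord])

    road_d = _road_distance_m(scenario, lats, lons)
    diur_bg = _diurnal_background(hod, scenario.background_diurnal_amp)
    diur_tr = _diurnal_traffic(hod)

    values: Dict[Tuple[Pollutant, Component], np.ndarray] = {}
    for pi, pol in enumerate(Pollutant):
        spatial = _spatial_surface(scenario, pol, lats, lons)  # (n_c,)
        bg = (scenario.background_mean[pol] * spatial[None, :]
              * diur_bg[:, None] * bg_day[:, pi][:, None])
        onr_space = np.zeros_like(spatial)
        for road, d in zip(scenario.roads, road_d):
            onr_space = onr_space + road.peak_ugm3[pol] * np.exp(-d / scenario.onroad_decay_m)
        onr = onr_space[None, :] * diur_tr[:, None] * onr_day[:, pi][:, None]
        values[(pol, Component.BACKGROUND)] = bg
        values[(pol, Component.ONROAD)] = onr
        values[(pol, Component.TOTAL)] = bg + onr
    return ConcentrationField(ids, lats, lons, hours, values)


def generate_weather(scenario: StudyScenario, dates: Sequence[Date],
                     day_start_hour: int = DAY_START_HOUR) -> pd.DataFrame:
    """Hourly outdoor temperature (C) and wind speed (m/s) for the study hours."""
    hours = study_hours(dates, day_start_hour)
    doy = hours.dayofyear.to_numpy()
    hod = hours.hour.to_numpy()
    seasonal = 15.0 - 9.0 * np.cos(2.0 * np.pi * (doy - 15) / 365.25)
    diurnal = -4.0 * np.cos(2.0 * np.pi * (hod - 15) / 24.0)
    day_ord = np.array([ts.date().toordinal() for ts in hours])
    t = np.empty(len(hours))
    w = np.empty(len(hours))
    for d in np.unique(day_ord):
        rng = _rng(scenario.seed, _S_WEATHER, int(d))
        m = day_ord == d
        t[m] = rng.normal(0.0, 1.2, m.sum())
        w[m] = np.abs(rng.normal(3.0, 1.5, m.sum()))
    return pd.DataFrame({"t_out_c": seasonal + diurnal + t, "wind_mps": w}, index=hours)


Cohort = Dict[str, Tuple[Participant, HomeModel, PlaceGeometry]]


def generate_cohort(scenario: StudyScenario) -> Cohort:
    """Participants with homes, building models and place geometries."""
    rng = _rng(scenario.seed, _S_COHORT)
    cohort: Cohort = {}
    lat_span = scenario.lat_max - scenario.lat_min
    lon_span = scenario.lon_max - scenario.lon_min
    for i in range(scenario.n_participants):
        pid = f"P{i + 1:02d}"
        sex = Sex.MALE if rng.random() < 0.6 else Sex.FEMALE
        age = float(rng.uniform(45, 78))
        height = float(rng.normal(176, 7) if sex == Sex.MALE else rng.normal(163, 6))
        weight = float(rng.normal(88, 14) if sex == Sex.MALE else rng.normal(74, 13))
        home_lat = scenario.lat_min + lat_span * rng.uniform(0.1, 0.9)
        home_lon = scenario.lon_min + lon_span * rng.uniform(0.1, 0.9)
        has_work = rng.random() < 0.7
        if has_work:
            work_lat = scenario.lat_min + lat_span * rng.uniform(0.1, 0.9)
            work_lon = scenario.lon_min + lon_span * rng.uniform(0.1, 0.9)
        else:
            work_lat = work_lon = None
        participant = Participant(pid, age, sex, max(height, 140.0),
                                  max(weight, 45.0), home_lat, home_lon,
                                  work_lat, work_lon)
        home = HomeModel(id=f"H{i + 1:02d}",
                         a_leak_m2=float(rng.uniform(0.03, 0.10)),
                         volume_m3=float(rng.uniform(250, 600)),
                         openable_area_m2=float(rng.uniform(0.5, 2.0)),
                         fan_flow_m3h=float(rng.uniform(800, 2000)),
                         stories=int(rng.integers(1, 3)),
                         shielding_class=int(rng.integers(3, 6)))
        places = PlaceGeometry(home_lat=home_lat, home_lon=home_lon,
                               work_lat=work_lat, work_lon=work_lon)
        cohort[pid] = (participant, home, places)
    return cohort


def generate_clinic_days(scenario: StudyScenario) -> List[Tuple[str, Date]]:
    """Clinic participant-days: consecutive weekdays (Tue+Wed) per visit week."""
    rng = _rng(scenario.seed, _S_SCHED)
    out: List[Tuple[str, Date]] = []
    for i in range(scenario.n_participants):
        pid = f"P{i + 1:02d}"
        weeks = rng.choice(scenario.n_weeks, size=scenario.visit_weeks_per_participant,
                           replace=False)
        for wk in sorted(int(w) for w in weeks):
            monday = scenario.start_date + timedelta(weeks=wk)
            monday -= timedelta(days=monday.weekday())
            for j in range(scenario.clinic_days_per_visit):
                out.append((pid, monday + timedelta(days=1 + j)))  # Tue, Wed, ...
    return out


def schedule_study(clinic_days: Sequence[Tuple[str, Date]],
                   n_lags: int = 5) -> List[ScheduledDay]:
    """Each clinic day contributes itself plus its ``n_lags`` preceding days.

    Days are scheduled with multiplicity when clinic days are close
    together; unique participant-days can be counted from the result.
    """
    if n_lags < 0:
        raise ValueError("n_lags must be >= 0")
    out: List[ScheduledDay] = []
    for pid, clinic in clinic_days:
        for lag in range(n_lags, -1, -1):
            out.append(ScheduledDay(pid, clinic - timedelta(days=lag), clinic))
    return out


# ---------------------------------------------------------------------------
# participant-day realization

def _plan_segments(scenario: StudyScenario, places: PlaceGeometry, day: Date,
                   rng: np.random.Generator) -> List[Tuple[int, int, float]]:
    """Ground-truth day plan as (ME7 code, duration_ticks, pal) segments.

    The plan starts at 8 am; commute durations derive from the home-work
    distance at the scenario drive speed, keeping generated speeds above
    any sensible vehicle-detection threshold.
    """
    from .microtrac import haversine_m

    def minutes(m: float) -> int:
        return max(1, int(round(m * 60 / TICK_SECONDS)))

    is_weekend = day.weekday() >= 5
    workday = places.has_work and not is_weekend
    segs: List[Tuple[int, int, float]] = []
    if workday:
        commute_km = haversine_m(places.home_lat, places.home_lon,
                                 places.work_lat, places.work_lon) / 1000.0
        commute_min = max(6.0, 60.0 * commute_km / scenario.drive_speed_kmh)
        segs += [
            (ME7.IN_HOME, minutes(rng.uniform(20, 40)), PalLevel.LIGHT),
            (ME7.IN_VEHICLE, minutes(commute_min), PalLevel.LIGHT),
            (ME7.IN_WORK, minutes(rng.uniform(200, 230)), PalLevel.SEDENTARY),
            (ME7.OUT_WORK, minutes(rng.uniform(15, 25)), PalLevel.LIGHT),
            (ME7.IN_WORK, minutes(rng.uniform(230, 260)), PalLevel.SEDENTARY),
            (ME7.IN_VEHICLE, minutes(commute_min), PalLevel.LIGHT),
            (ME7.OUT_HOME, minutes(rng.uniform(20, 40)), PalLevel.MODERATE),
        ]
    else:
        errand_min = rng.uniform(10, 16)
        segs += [
            (ME7.IN_HOME, minutes(rng.uniform(90, 130)), PalLevel.SEDENTARY),
            (ME7.OUT_HOME, minutes(rng.uniform(30, 50)), PalLevel.MODERATE),
            (ME7.IN_HOME, minutes(rng.uniform(60, 120)), PalLevel.LIGHT),
            (ME7.IN_VEHICLE, minutes(errand_min), PalLevel.LIGHT),
            (ME7.IN_OTHER, minutes(rng.uniform(45, 80)), PalLevel.LIGHT),
            (ME7.OUT_OTHER, minutes(rng.uniform(10, 20)), PalLevel.LIGHT),
            (ME7.IN_VEHICLE, minutes(errand_min), PalLevel.LIGHT),
            (ME7.OUT_HOME, minutes(rng.uniform(10, 25)), PalLevel.LIGHT),
        ]
    used = sum(d for _, d, _ in segs)
    segs.append((ME7.IN_HOME, TICKS_PER_DAY - used, PalLevel.SEDENTARY))
    if segs[-1][1] <= 0:
        raise ValueError("day plan exceeds 24 h")
    return segs


def _other_place(scenario: StudyScenario, places: PlaceGeometry,
                 rng: np.random.Generator) -> Tuple[float, float]:
    """A destination 2-6 km from home for errands."""
    ang = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(2000, 6000)
    dlat = dist * np.cos(ang) / 110_540.0
    dlon = dist * np.sin(ang) / (111_320.0 * math.cos(math.radians(places.home_lat)))
    return places.home_lat + dlat, places.home_lon + dlon


def generate_participant_day(scenario: StudyScenario, places: PlaceGeometry,
                             participant_index: int, day: Date,
                             day_start_hour: int = DAY_START_HOUR
                             ) -> Tuple[pd.DataFrame, np.ndarray,
                                        QuestionnaireDay, MicroenvSeries]:
    """Realize one observed participant-day.

    Returns (GPS track, 1-s accelerometer counts, questionnaire,
    ground-truth 7-class ME series).
    """
    rng = _rng(scenario.seed, _S_DAY, participant_index, day.toordinal())
    segs = _plan_segments(scenario, places, day, rng)
    other = _other_place(scenario, places, rng)

    truth = np.concatenate([np.full(d, int(me), dtype=np.int8) for me, d, _ in segs])
    pal_plan = np.concatenate([np.full(d, int(p), dtype=np.int8) for _, d, p in segs])
    ticks = day_ticks(day, day_start_hour)

    centers = {
        ME7.IN_HOME: (places.home_lat, places.home_lon),
        ME7.OUT_HOME: (places.home_lat, places.home_lon),
        ME7.IN_WORK: (places.work_lat, places.work_lon),
        ME7.OUT_WORK: (places.work_lat, places.work_lon),
        ME7.IN_OTHER: other,
        ME7.OUT_OTHER: other,
    }

    lat = np.empty(TICKS_PER_DAY)
    lon = np.empty(TICKS_PER_DAY)
    speed = np.zeros(TICKS_PER_DAY)
    pos = 0
    for si, (me, dur, _) in enumerate(segs):
        sl = slice(pos, pos + dur)
        if me == ME7.IN_VEHICLE:
            prev_me = segs[si - 1][0]
            next_me = segs[si + 1][0] if si + 1 < len(segs) else ME7.IN_HOME
            a = centers[prev_me]
            b = centers[next_me]
            frac = np.linspace(0.0, 1.0, dur)
            lat[sl] = a[0] + (b[0] - a[0]) * frac
            lon[sl] = a[1] + (b[1] - a[1]) * frac
            from .microtrac import haversine_m
            seg_kmh = (haversine_m(a[0], a[1], b[0], b[1]) / 1000.0) \
                / (dur * TICK_SECONDS / 3600.0)
            seg_kmh = max(seg_kmh, 20.0)
            speed[sl] = np.clip(seg_kmh + rng.normal(0, 3.0, dur), 15.0, None)
        else:
            c = centers[me]
            noise = rng.normal(0.0, scenario.position_noise_m, size=(dur, 2))
            lat[sl] = c[0] + noise[:, 0] / 110_540.0
            lon[sl] = c[1] + noise[:, 1] / (111_320.0 * math.cos(math.radians(c[0])))
            indoor = me in (ME7.IN_HOME, ME7.IN_WORK, ME7.IN_OTHER)
            speed[sl] = np.abs(rng.normal(0.0 if indoor else 1.5,
                                          0.5 if indoor else 1.0, dur))
        pos += dur

    indoor_mask = np.isin(truth, [ME7.IN_HOME, ME7.IN_WORK, ME7.IN_OTHER])
    vehicle_mask = truth == ME7.IN_VEHICLE
    fix_prob = np.where(indoor_mask, scenario.indoor_fix_prob,
                        np.where(vehicle_mask, scenario.vehicle_fix_prob,
                                 scenario.outdoor_fix_prob))
    valid = rng.random(TICKS_PER_DAY) < fix_prob
    pdop = np.where(
        indoor_mask,
        np.exp(rng.normal(scenario.indoor_pdop_logmean,
                          scenario.indoor_pdop_logsd, TICKS_PER_DAY)),
        np.exp(rng.normal(scenario.outdoor_pdop_logmean,
                          scenario.outdoor_pdop_logsd, TICKS_PER_DAY)))
    pdop = np.maximum(pdop, 1.0)
    nsat = np.where(indoor_mask, 4, 8)

    track = pd.DataFrame({
        "timestamp": ticks,
        "lat": np.where(valid, lat, np.nan),
        "lon": np.where(valid, lon, np.nan),
        "speed_kmh": np.where(valid, speed, np.nan),
        "nsat": np.where(valid, nsat, 0),
        "pdop": np.where(valid, pdop, np.nan),
        "valid": valid,
    })

    # accelerometer: 1-s Poisson counts at the planned-activity mean;
    # in-vehicle ticks emit light-level counts (vehicle vibration), which
    # the in-vehicle PAL override is there to correct
    means = np.array([scenario.counts_per_s[i] for i in range(4)])
    per_s_mean = np.repeat(means[pal_plan], TICK_SECONDS)
    counts = rng.poisson(per_s_mean).astype(np.int64)

    # questionnaire driven by season
    qrng = _rng(scenario.seed, _S_QUEST, participant_index, day.toordinal())
    mild = day.month in (4, 5, 9, 10)
    summer = day.month in (6, 7, 8)
    quest = QuestionnaireDay(
        date=day,
        t_in_c=float(qrng.normal(20.5, 1.2)),
        windows_open=bool(qrng.random() < (0.5 if mild else 0.08)),
        doors_open=bool(qrng.random() < 0.1),
        fan_on=bool(qrng.random() < (0.25 if summer else 0.02)),
    )
    return track, counts, quest, MicroenvSeries(ticks, truth, n_classes=7)


@dataclass
class StudyData:
    """Everything run_study needs, plus the generator's ground truth."""

    scenario: StudyScenario
    cohort: Cohort
    clinic_days: List[Tuple[str, Date]]
    schedule: List[ScheduledDay]
    fields: Dict[Date, ConcentrationField]
    weather: pd.DataFrame
    questionnaires: Dict[Tuple[str, Date], QuestionnaireDay]
    tracks: Dict[Tuple[str, Date], pd.DataFrame]
    accel: Dict[Tuple[str, Date], np.ndarray]
    truth_me: Dict[Tuple[str, Date], MicroenvSeries]


def generate_study(scenario: StudyScenario,
                   day_start_hour: int = DAY_START_HOUR) -> StudyData:
    """Generate the complete synthetic study for the scenario."""
    cohort = generate_cohort(scenario)
    clinic_days = generate_clinic_days(scenario)
    schedule = schedule_study(clinic_days, scenario.n_lags)
    all_dates = sorted({s.date for s in schedule})

    one_field = generate_field(scenario, all_dates, day_start_hour)
    fields = {d: one_field for d in all_dates}
    weather = generate_weather(scenario, all_dates, day_start_hour)

    questionnaires: Dict[Tuple[str, Date], QuestionnaireDay] = {}
    tracks: Dict[Tuple[str, Date], pd.DataFrame] = {}
    accel: Dict[Tuple[str, Date], np.ndarray] = {}
    truth: Dict[Tuple[str, Date], MicroenvSeries] = {}
    pid_index = {pid: i for i, pid in enumerate(cohort)}
    for pid, day in clinic_days:
        _, _, places = cohort[pid]
        track, counts, quest, me = generate_participant_day(
            scenario, places, pid_index[pid], day, day_start_hour)
        key = (pid, day)
        tracks[key], accel[key], questionnaires[key], truth[key] = (
            track, counts, quest, me)
    return StudyData(scenario, cohort, clinic_days, schedule, fields, weather,
                     questionnaires, tracks, accel, truth)
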