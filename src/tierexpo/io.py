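"""CSV readers/writers for every external table, plus run configuration.

Dialect: comma-separated, UTF-8, header row, '.' decimal.  Timestamps
are ISO-8601 in local study time.  Every writer's output round-trips
through its reader.
"""

from __future__ import annotations

import logging
from datetime import date as Date
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .aer import QuestionnaireDay
from .core import Component, Pollutant
from .octrac import ConcentrationField

logger = logging.getLogger("tierexpo")

GPS_COLUMNS = ["date", "time", "lat", "lon", "speed_kmh", "nsat", "pdop", "valid"]


def read_gps(path) -> pd.DataFrame:
    """Read a GPS logger CSV into a validated, time-sorted track.

    Columns: date, time, lat, lon, speed_kmh, nsat, pdop, valid.
    Malformed rows and rows violating pdop >= 1 on a valid fix are
    logged and skipped.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GPS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"GPS file {path} is missing columns {missing}")
    n_bad = 0
    rows = []
    for _, r in raw.iterrows():
        try:
            ts = pd.Timestamp(f"{r['date']} {r['time']}")
            valid = r["valid"].strip() in ("1", "True", "true")
            lat = float(r["lat"]) if r["lat"] != "" else np.nan
            lon = float(r["lon"]) if r["lon"] != "" else np.nan
            speed = float(r["speed_kmh"]) if r["speed_kmh"] != "" else np.nan
            nsat = int(float(r["nsat"])) if r["nsat"] != "" else 0
            pdop = float(r["pdop"]) if r["pdop"] != "" else np.nan
            if valid and (np.isnan(lat) or np.isnan(lon) or not pdop >= 1.0):
                raise ValueError("valid fix needs position and pdop >= 1")
            rows.append((ts, lat, lon, speed, nsat, pdop, valid))
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.warning("read_gps(%s): skipped %d malformed row(s)", path, n_bad)
    if not rows:
        raise ValueError(f"GPS file {path} contains no valid rows")
    track = pd.DataFrame(rows, columns=["timestamp", "lat", "lon", "speed_kmh",
                                        "nsat", "pdop", "valid"])
    return track.sort_values("timestamp", kind="stable").reset_index(drop=True)


def write_gps(track: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "date": track["timestamp"].dt.strftime("%Y-%m-%d"),
        "time": track["timestamp"].dt.strftime("%H:%M:%S"),
        "lat": track["lat"],
        "lon": track["lon"],
        "speed_kmh": track["speed_kmh"],
        "nsat": track["nsat"].fillna(0).astype(int),
        "pdop": track["pdop"],
        "valid": track["valid"].astype(int),
    })
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    """Weather CSV: timestamp, t_out_c, wind_mps, indexed by timestamp."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df = df.set_index("timestamp").sort_index()
    if (df["wind_mps"] < 0).any():
        raise ValueError("wind speed must be nonnegative")
    return df[["t_out_c", "wind_mps"]]


def write_weather(weather: pd.DataFrame, path) -> None:
    out = weather.reset_index(names="timestamp")
    out.to_csv(path, index=False)


def read_questionnaires(path) -> Dict[Tuple[str, Date], QuestionnaireDay]:
    """Questionnaire CSV: date, home_id, t_in_c, windows_open, doors_open, fan_on."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for _, r in df.iterrows():
        q = QuestionnaireDay(date=r["date"].date(), t_in_c=float(r["t_in_c"]),
                             windows_open=bool(int(r["windows_open"])),
                             doors_open=bool(int(r["doors_open"])),
                             fan_on=bool(int(r["fan_on"])))
        out[(str(r["home_id"]), q.date)] = q
    return out


def write_questionnaires(quests: Dict[Tuple[str, Date], QuestionnaireDay], path) -> None:
    rows = [{"date": d.isoformat(), "home_id": hid, "t_in_c": q.t_in_c,
             "windows_open": int(q.windows_open), "doors_open": int(q.doors_open),
             "fan_on": int(q.fan_on)}
            for (hid, d), q in sorted(quests.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


FIELD_COLUMNS = ["centroid_id", "lat", "lon", "timestamp_hour", "pollutant",
                 "component", "conc_ugm3"]


def read_field(path) -> ConcentrationField:
    """Field CSV (long format) into a ConcentrationField."""
    df = pd.read_csv(path)
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"field file {path} is missing columns {missing}")
    df["timestamp_hour"] = pd.to_datetime(df["timestamp_hour"])
    cents = (df[["centroid_id", "lat", "lon"]].drop_duplicates("centroid_id")
             .sort_values("centroid_id"))
    ids = cents["centroid_id"].to_numpy()
    hours = pd.DatetimeIndex(np.sort(df["timestamp_hour"].unique()))
    id_pos = {cid: i for i, cid in enumerate(ids)}
    hr_pos = {h: i for i, h in enumerate(hours)}
    values = {}
    for (pol, comp), grp in df.groupby(["pollutant", "component"]):
        arr = np.full((len(hours), len(ids)), np.nan)
        arr[grp["timestamp_hour"].map(hr_pos).to_numpy(),
            grp["centroid_id"].map(id_pos).to_numpy()] = grp["conc_ugm3"].to_numpy()
        if np.isnan(arr).any():
            raise ValueError(f"field {pol}/{comp} has missing centroid-hours")
        values[(Pollutant(pol), Component(comp))] = arr
    return ConcentrationField(ids, cents["lat"].to_numpy(), cents["lon"].to_numpy(),
                              hours, values)


def write_field(fld: ConcentrationField, path) -> None:
    frames = []
    for (pol, comp), arr in fld.values.items():
        n_h, n_c = arr.shape
        frames.append(pd.DataFrame({
            "centroid_id": np.tile(fld.centroid_ids, n_h),
            "lat": np.tile(fld.lats, n_h),
            "lon": np.tile(fld.lons, n_h),
            "timestamp_hour": np.repeat(fld.hours, n_c),
            "pollutant": pol.value,
            "component": comp.value,
            "conc_ugm3": arr.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_accel(path) -> Tuple[pd.DatetimeIndex, np.ndarray]:
    """Accelerometer CSV: timestamp, counts (1-s epochs)."""
    df = pd.read_csv(path, parse_dates=["timestamp"]).sort_values("timestamp")
    counts = df["counts"].to_numpy()
    if np.any(counts < 0) or not np.all(counts == counts.astype(np.int64)):
        raise ValueError("activity counts must be nonnegative integers")
    return pd.DatetimeIndex(df["timestamp"]), counts.astype(np.int64)


def write_accel(timestamps: pd.DatetimeIndex, counts: np.ndarray, path) -> None:
    pd.DataFrame({"timestamp": timestamps, "counts": counts}).to_csv(path, index=False)


def read_nmv_table(path):
    from .vtrac import NmvTable
    return NmvTable(pd.read_csv(path))


def write_nmv_table(nmv, path) -> None:
    nmv.table.to_csv(path, index=False)


def write_tier_records(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_tier_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return df


def write_cohort(cohort, path) -> None:
    """Cohort CSV: participant anthropometrics + home model + place geometry."""
    rows = []
    for pid, (p, h, g) in cohort.items():
        rows.append({
            "participant": pid, "age": p.age, "sex": p.sex.value,
            "body_height_cm": p.body_height_cm, "body_weight_kg": p.body_weight_kg,
            "home_lat": p.home_lat, "home_lon": p.home_lon,
            "work_lat": p.work_lat if p.has_work else "",
            "work_lon": p.work_lon if p.has_work else "",
            "home_id": h.id, "a_leak_m2": h.a_leak_m2, "volume_m3": h.volume_m3,
            "openable_area_m2": h.openable_area_m2, "fan_flow_m3h": h.fan_flow_m3h,
            "stories": h.stories, "shielding_class": h.shielding_class,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path):
    from .aer import HomeModel
    from .core import Participant, Sex
    from .microtrac import PlaceGeometry

    df = pd.read_csv(path)
    cohort = {}
    for _, r in df.iterrows():
        work_lat = float(r["work_lat"]) if pd.notna(r["work_lat"]) else None
        work_lon = float(r["work_lon"]) if pd.notna(r["work_lon"]) else None
        p = Participant(str(r["participant"]), float(r["age"]), Sex(r["sex"]),
                        float(r["body_height_cm"]), float(r["body_weight_kg"]),
                        float(r["home_lat"]), float(r["home_lon"]),
                        work_lat, work_lon)
        h = HomeModel(id=str(r["home_id"]), a_leak_m2=float(r["a_leak_m2"]),
                      volume_m3=float(r["volume_m3"]),
                      openable_area_m2=float(r["openable_area_m2"]),
                      fan_flow_m3h=float(r["fan_flow_m3h"]),
                      stories=int(r["stories"]),
                      shielding_class=int(r["shielding_class"]))
        g = PlaceGeometry(home_lat=p.home_lat, home_lon=p.home_lon,
                          work_lat=work_lat, work_lon=work_lon)
        cohort[p.id] = (p, h, g)
    return cohort


def write_schedule(schedule, path) -> None:
    rows = [{"participant": s.participant_id, "date": s.date.isoformat(),
             "clinic_date": s.clinic_date.isoformat()} for s in schedule]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedule(path):
    from .tiers import ScheduledDay

    df = pd.read_csv(path, parse_dates=["date", "clinic_date"])
    return [ScheduledDay(str(r["participant"]), r["date"].date(),
                         r["clinic_date"].date()) for _, r in df.iterrows()]


class RunConfig(BaseModel):
    """Paths and options of a `tierexpo run` invocation (TOML).

    Unknown keys are rejected so typos fail loudly.
    """

    model_config = ConfigDict(extra="forbid")

    field_csv: str
    weather_csv: str
    questionnaire_csv: str
    gps_dir: str
    accel_dir: str
    nmv_csv: Optional[str] = None
    cohort_csv: str = "cohort.csv"
    schedule_csv: str = "schedule.csv"
    output_csv: str = "tier_records.csv"
    day_start_hour: int = 8
    log_level: str = "INFO"
    pollutants: Dict[str, Dict[str, float]] = {}


def load_config(path) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(**data)
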