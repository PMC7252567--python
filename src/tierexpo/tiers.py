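"""Assembly of the five tiers of daily exposure metrics.

Per participant-day, pollutant and source component the pipeline yields:

* Tier 1 — home outdoor concentration (24-h mean of the hourly field at
  the home centroid);
* Tier 2 — home indoor concentration (24-h mean of the mass-balance
  infiltration series);
* Tier 3 — personal outdoor concentration (24-h mean of the 5-s
  GPS-matched series);
* Tier 4 — exposure, a microenvironment-weighted blend of the home
  indoor and personal outdoor series:

      E = ME_in_home * C_in_home
        + [(ME_in_work + ME_in_other) * F_inf_other_bldg
           + ME_in_vehicle * F_inf_vehicle + ME_out] * C_out_personal

* Tier 5 — inhaled dose accumulated over the day, D_i = E_i * MV * AT /
  BSA per microenvironment i, with AT the 5-s tick length in minutes
  and BSA the DuBois body surface area.

All tiers are linear in concentration, so background and on-road
records add to the total record field-by-field.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aer import HomeModel, QuestionnaireDay, hourly_aer
from .core import (DAY_START_HOUR, TICKS_PER_DAY, TICK_SECONDS, Component,
                   Participant, Pollutant, PollutantParams,
                   default_pollutant_params)
from .infiltration import indoor_series
from .microtrac import (ME5, ME7, MicroenvSeries, PlaceGeometry, classify_me,
                        collapse_to_five, lag_day_me)
from .octrac import (ConcentrationField, lag_day_geolocation, nearest_centroid,
                     series_from_indices, track_field_indices)
from .vtrac import NmvTable, minute_ventilation_series, pal_series

#: Tick length in minutes (5 s exactly).
AT_MIN = TICK_SECONDS / 60.0


@dataclass
class TierRecord:
    """All five tier metrics for one participant-day x pollutant x component."""

    participant: str
    date: Date
    pollutant: Pollutant
    component: Component
    tier1_c_out_home: float
    tier2_c_in_home: float
    tier3_c_out_personal: float
    tier4_exposure: float
    tier5_dose_total: float
    dose_by_me: np.ndarray  # 7-vector, ug/m2 BSA
    time_by_me: np.ndarray  # 7-vector, minutes
    imputed: bool = False

    def validate(self, rel_tol: float = 1e-9) -> None:
        vals = [self.tier1_c_out_home, self.tier2_c_in_home,
                self.tier3_c_out_personal, self.tier4_exposure,
                self.tier5_dose_total]
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise ValueError("tier metrics must be finite and nonnegative")
        dose_sum = float(np.sum(self.dose_by_me))
        scale = max(abs(self.tier5_dose_total), 1e-300)
        if abs(dose_sum - self.tier5_dose_total) / scale > rel_tol:
            raise ValueError("dose_by_me does not sum to the total dose")
        if abs(float(np.sum(self.time_by_me)) - 1440.0) > 1e-9:
            raise ValueError("time_by_me must sum to 1440 minutes")


def exposure_tick(me5_onehot: np.ndarray, c_in_home, c_out_pers,
                  params: PollutantParams):
    """Microenvironment-weighted exposure at one tick (or vectorized).

    ``me5_onehot`` has shape (..., 5) in the order in_home, in_work,
    in_other, in_vehicle, outdoors and must be one-hot.
    """
    oh = np.asarray(me5_onehot)
    if oh.shape[-1] != 5 or np.any(oh.sum(axis=-1) != 1) or np.any((oh != 0) & (oh != 1)):
        raise ValueError("microenvironment indicators must be one-hot over 5 classes")
    c_in = np.asarray(c_in_home, dtype=float)
    c_out = np.asarray(c_out_pers, dtype=float)
    if np.any(c_in < 0) or np.any(c_out < 0):
        raise ValueError("concentrations must be nonnegative")
    e = (oh[..., ME5.IN_HOME] * c_in
         + ((oh[..., ME5.IN_WORK] + oh[..., ME5.IN_OTHER]) * params.f_inf_other_bldg
            + oh[..., ME5.IN_VEHICLE] * params.f_inf_vehicle
            + oh[..., ME5.OUTDOORS]) * c_out)
    return float(e) if e.ndim == 0 else e


def dose_tick(e_by_me: np.ndarray, mv_m3_min, bsa_m2: float):
    """Per-ME dose increments D_i = E_i * MV * AT / BSA (ug/m2)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    mv = np.asarray(mv_m3_min, dtype=float)
    if np.any(mv < 0):
        raise ValueError("MV must be nonnegative")
    return np.asarray(e_by_me, dtype=float) * mv * AT_MIN / bsa_m2


def _exposure_by_me7(me7: MicroenvSeries, c_in_ticks: np.ndarray,
                     c_out_ticks: np.ndarray, params: PollutantParams) -> np.ndarray:
    """(n_ticks, 7) per-ME exposures; only the occupied ME is nonzero."""
    factors = np.array([np.nan, params.f_inf_other_bldg, params.f_inf_other_bldg,
                        params.f_inf_vehicle, 1.0, 1.0, 1.0])
    oh = me7.one_hot().astype(float)
    e = oh * factors[None, :] * c_out_ticks[:, None]
    e[:, ME7.IN_HOME] = oh[:, ME7.IN_HOME] * c_in_ticks
    return e


def daily_metrics(participant: Participant, day: Date, pollutant: Pollutant,
                  component: Component, me7: MicroenvSeries,
                  c_out_home_hourly: pd.Series, c_in_home_hourly: pd.Series,
                  c_out_personal_ticks: pd.Series, mv_ticks: np.ndarray,
                  params: PollutantParams, imputed: bool = False) -> TierRecord:
    """Build the TierRecord for one participant-day x pollutant x component.

    Hourly series carry 24 values over the 8am-8am window; tick series
    carry 17,280.  The hourly indoor series is held piecewise-constant
    within each hour when sampled at tick cadence.
    """
    for s, n in ((c_out_home_hourly, 24), (c_in_home_hourly, 24),
                 (c_out_personal_ticks, TICKS_PER_DAY)):
        if len(s) != n:
            raise ValueError(f"series covering the 24-h window expected "
                             f"({n} values, got {len(s)})")
    c_in_ticks = np.repeat(c_in_home_hourly.to_numpy(dtype=float), TICKS_PER_DAY // 24)
    c_out_ticks = c_out_personal_ticks.to_numpy(dtype=float)

    e_by_me = _exposure_by_me7(me7, c_in_ticks, c_out_ticks, params)
    e_ticks = e_by_me.sum(axis=1)
    d_by_me = dose_tick(e_by_me, np.asarray(mv_ticks)[:, None], participant.body_surface_area_m2)

    rec = TierRecord(
        participant=participant.id,
        date=day,
        pollutant=pollutant,
        component=component,
        tier1_c_out_home=float(c_out_home_hourly.mean()),
        tier2_c_in_home=float(c_in_home_hourly.mean()),
        tier3_c_out_personal=float(c_out_ticks.mean()),
        tier4_exposure=float(e_ticks.mean()),
        tier5_dose_total=float(d_by_me.sum()),
        dose_by_me=d_by_me.sum(axis=0),
        time_by_me=me7.time_by_me_minutes(),
        imputed=imputed,
    )
    rec.validate(rel_tol=1e-6)
    return rec


@dataclass(frozen=True)
class ScheduledDay:
    """One modeled participant-day: the date plus the clinic day it derives from."""

    participant_id: str
    date: Date
    clinic_date: Date

    @property
    def is_clinic_day(self) -> bool:
        return self.date == self.clinic_date

    @property
    def is_weekend(self) -> bool:
        return self.date.weekday() >= 5


ME_COLUMNS = ["in_home", "in_work", "in_other", "in_vehicle",
              "out_home", "out_work", "out_other"]


def records_to_frame(records: Iterable[TierRecord]) -> pd.DataFrame:
    """Tidy DataFrame: one row per TierRecord."""
    rows = []
    for r in records:
        row = {
            "participant": r.participant,
            "date": r.date,
            "pollutant": r.pollutant.value,
            "component": r.component.value,
            "tier1": r.tier1_c_out_home,
            "tier2": r.tier2_c_in_home,
            "tier3": r.tier3_c_out_personal,
            "tier4": r.tier4_exposure,
            "tier5": r.tier5_dose_total,
        }
        for i, name in enumerate(ME_COLUMNS):
            row[f"dose_{name}"] = r.dose_by_me[i]
        for i, name in enumerate(ME_COLUMNS):
            row[f"time_{name}"] = r.time_by_me[i]
        row["imputed"] = r.imputed
        rows.append(row)
    return pd.DataFrame(rows)


class StudyRunError(RuntimeError):
    """A stage failure wrapped with participant-day context."""


def run_study(cohort: Mapping[str, Tuple[Participant, HomeModel, PlaceGeometry]],
              fields: Mapping[Date, ConcentrationField],
              weather: pd.DataFrame,
              questionnaires: Mapping[Tuple[str, Date], QuestionnaireDay],
              tracks: Mapping[Tuple[str, Date], pd.DataFrame],
              accel: Mapping[Tuple[str, Date], np.ndarray],
              schedule: Sequence[ScheduledDay],
              nmv: NmvTable,
              params: Optional[Mapping[Pollutant, PollutantParams]] = None,
              day_start_hour: int = DAY_START_HOUR) -> List[TierRecord]:
    """Run the full pipeline over a study schedule.

    ``tracks``, ``accel`` and ``questionnaires`` are keyed by
    (participant, clinic date); lag days are imputed with the copy rules
    (weekend work-to-home substitution included).  Returns one record
    per scheduled day x 4 pollutants x 3 components.
    """
    if params is None:
        params = default_pollutant_params()

    # Per-clinic-day caches are valid while the schedule stays on the same
    # clinic day, so group the work accordingly and keep only one cache.
    ordered = sorted(schedule, key=lambda s: (s.participant_id, s.clinic_date, s.date))
    records: List[TierRecord] = []
    cache_key = None
    cache: Dict = {}

    for entry in ordered:
        try:
            participant, home, places = cohort[entry.participant_id]
            key = (entry.participant_id, entry.clinic_date)
            if key != cache_key:
                track = tracks[key]
                me7_clinic = classify_me(track, places, day=entry.clinic_date,
                                         day_start_hour=day_start_hour)
                counts = np.asarray(accel[key])
                cache = {"track": track, "me7": me7_clinic, "counts": counts,
                         "quest": questionnaires[key], "indices": {}}
                cache_key = key

            fld = fields[entry.date]
            is_lag = not entry.is_clinic_day
            if is_lag:
                me7 = lag_day_me(cache["me7"], entry.date, entry.is_weekend,
                                 day_start_hour)
                quest = cache["quest"].for_lag_day(entry.date)
            else:
                me7 = cache["me7"]
                quest = cache["quest"]

            # centroid indices depend only on geometry (weekend relocation
            # included), so cache per weekend flag
            geo_key = bool(is_lag and entry.is_weekend)
            if geo_key not in cache["indices"]:
                track = cache["track"]
                if geo_key:
                    track = lag_day_geolocation(track, entry.date, True, places,
                                                day_start_hour)
                    cent = fld.nearest_centroid_index(*_grid_positions(track, entry.date,
                                                                       day_start_hour))
                else:
                    cent = fld.nearest_centroid_index(*_grid_positions(track,
                                                                       entry.clinic_date,
                                                                       day_start_hour))
                cache["indices"][geo_key] = cent
            cent_idx = cache["indices"][geo_key]

            from .aer import day_window
            hours = day_window(entry.date, day_start_hour)
            hour_pos = fld.hour_positions(hours)
            per_tick_hour = hour_pos[np.arange(TICKS_PER_DAY) // (TICKS_PER_DAY // 24)]
            ticks = _ticks_for(entry.date, day_start_hour)

            home_cent = int(fld.nearest_centroid_index(participant.home_lat,
                                                       participant.home_lon)[0])
            aer = hourly_aer(home, weather, quest, day_start_hour)

            pal = pal_series(cache["counts"], me7)
            mv = minute_ventilation_series(pal, participant, nmv)

            for pol in Pollutant:
                p = params[pol]
                for comp in Component:
                    c_out_home = pd.Series(
                        fld.values[(pol, comp)][hour_pos, home_cent], index=hours)
                    c_in = indoor_series(c_out_home, aer, p)
                    c_out_pers = series_from_indices(fld, pol, comp, per_tick_hour,
                                                     cent_idx, ticks)
                    records.append(daily_metrics(participant, entry.date, pol, comp,
                                                 me7, c_out_home, c_in, c_out_pers,
                                                 mv, p, imputed=is_lag))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StudyRunError(
                f"participant {entry.participant_id}, day {entry.date} "
                f"(clinic {entry.clinic_date}): {exc}") from exc
    return records


def _ticks_for(day: Date, day_start_hour: int) -> pd.DatetimeIndex:
    from .microtrac import day_ticks
    return day_ticks(day, day_start_hour)


def _grid_positions(track: pd.DataFrame, day: Date, day_start_hour: int):
    """Carried-forward (lat, lon) per tick on the day grid."""
    from .microtrac import align_track_to_grid, day_ticks
    g = align_track_to_grid(track, day_ticks(day, day_start_hour))
    return g["lat"].to_numpy(), g["lon"].to_numpy()
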