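"""Personal outdoor concentrations (Tier 3) by GPS-to-field matching.

Every 5-s GPS sample is matched in time to the enclosing hour of the
concentration field and in space to the nearest field centroid
(great-circle distance).  Missing fixes reuse the previous sample's
geolocation; a day that starts without a fix back-fills from the first
valid one.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DAY_START_HOUR, TICKS_PER_DAY, Component, Pollutant
from .microtrac import PlaceGeometry, align_track_to_grid, day_ticks, haversine_m

_REL_TOL_ADDITIVITY = 1e-9


class FieldCoverageError(ValueError):
    """Raised when the field does not cover a requested hour."""


@dataclass
class ConcentrationField:
    """Hourly concentrations at geolocated centroids.

    ``hours`` is a sorted, unique (not necessarily contiguous)
    DatetimeIndex; ``values`` maps (pollutant, component) to an array of
    shape (n_hours, n_centroids), ug/m3.  Totals must equal background
    plus on-road at every centroid-hour.
    """

    centroid_ids: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    hours: pd.DatetimeIndex
    values: Dict[Tuple[Pollutant, Component], np.ndarray]

    def __post_init__(self) -> None:
        n_c, n_h = len(self.centroid_ids), len(self.hours)
        if n_c == 0:
            raise ValueError("field has no centroids")
        if not self.hours.is_monotonic_increasing or self.hours.has_duplicates:
            raise ValueError("field hours must be sorted and unique")
        for key, arr in self.values.items():
            if arr.shape != (n_h, n_c):
                raise ValueError(f"values[{key}] has shape {arr.shape}, expected {(n_h, n_c)}")
            if np.any(arr < 0):
                raise ValueError(f"values[{key}] has negative concentrations")
        self._hour_pos = pd.Series(np.arange(n_h), index=self.hours)
        self.validate_additivity()

    def validate_additivity(self) -> None:
        for pol in Pollutant:
            keys = [(pol, c) for c in Component]
            if not all(k in self.values for k in keys):
                continue
            bg = self.values[(pol, Component.BACKGROUND)]
            onr = self.values[(pol, Component.ONROAD)]
            tot = self.values[(pol, Component.TOTAL)]
            scale = np.maximum(np.abs(tot), 1.0)
            if np.max(np.abs(tot - (bg + onr)) / scale) > 1e-9:
                raise ValueError(f"{pol.value}: total != background + onroad")

    def hour_positions(self, hours: pd.DatetimeIndex) -> np.ndarray:
        pos = self._hour_pos.reindex(hours)
        if pos.isna().any():
            missing = hours[pos.isna().to_numpy()]
            raise FieldCoverageError(
                f"field is missing {len(missing)} hour(s), first: {missing[0]}")
        return pos.to_numpy(dtype=np.int64)

    def nearest_centroid_index(self, lat, lon) -> np.ndarray:
        """Index (not id) of the nearest centroid for each query point."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        d = haversine_m(lat[:, None], lon[:, None], self.lats[None, :], self.lons[None, :])
        return np.argmin(d, axis=1)


def nearest_centroid(lat: float, lon: float, fld: ConcentrationField):
    """Id of the centroid nearest to (lat, lon), great-circle distance.

    Ties break deterministically to the lowest centroid id.
    """
    d = haversine_m(lat, lon, fld.lats, fld.lons)
    best = d.min()
    candidates = np.flatnonzero(d == best)
    return fld.centroid_ids[candidates[np.argmin(fld.centroid_ids[candidates])]]


def track_field_indices(track: pd.DataFrame, fld: ConcentrationField,
                        day: Optional[Date] = None,
                        day_start_hour: int = DAY_START_HOUR
                        ) -> Tuple[np.ndarray, np.ndarray, pd.DatetimeIndex]:
    """Per-tick (hour position, centroid index) for a day's track.

    Computing these once lets all pollutant x component series reuse the
    same spatial matching.
    """
    if day is None:
        first = track["timestamp"].iloc[0]
        day = (first - pd.Timedelta(hours=day_start_hour)).date()
    ticks = day_ticks(day, day_start_hour)
    g = align_track_to_grid(track, ticks)
    hour_idx = fld.hour_positions(pd.DatetimeIndex(ticks.floor("h").unique()))
    # every tick's hour position: ticks are 5-s within consecutive hours
    per_tick_hour = hour_idx[np.arange(TICKS_PER_DAY) // 720]
    cent_idx = fld.nearest_centroid_index(g["lat"].to_numpy(), g["lon"].to_numpy())
    return per_tick_hour, cent_idx, ticks


def series_from_indices(fld: ConcentrationField, pollutant: Pollutant,
                        component: Component, per_tick_hour: np.ndarray,
                        cent_idx: np.ndarray, ticks: pd.DatetimeIndex) -> pd.Series:
    vals = fld.values[(pollutant, component)][per_tick_hour, cent_idx]
    return pd.Series(vals, index=ticks, name="c_out_personal")


def personal_outdoor_series(track: pd.DataFrame, fld: ConcentrationField,
                            pollutant: Pollutant, component: Component,
                            day: Optional[Date] = None,
                            day_start_hour: int = DAY_START_HOUR) -> pd.Series:
    """5-s personal outdoor concentration series for one participant-day."""
    per_tick_hour, cent_idx, ticks = track_field_indices(track, fld, day, day_start_hour)
    return series_from_indices(fld, pollutant, component, per_tick_hour, cent_idx, ticks)


def lag_day_geolocation(track_day: pd.DataFrame, lag_date: Date, is_weekend: bool,
                        places: PlaceGeometry,
                        day_start_hour: int = DAY_START_HOUR) -> pd.DataFrame:
    """Impute a lag day's track by copying the observed day's geolocations.

    Timestamps are re-stamped to the lag date.  On weekend lag days any
    sample inside the work-place radius is relocated to the home center.
    """
    base_day = (track_day["timestamp"].iloc[0] - pd.Timedelta(hours=day_start_hour)).date()
    shift = pd.Timestamp(lag_date) - pd.Timestamp(base_day)
    out = track_day.copy()
    out["timestamp"] = out["timestamp"] + shift
    if is_weekend and places.has_work:
        d_work = haversine_m(out["lat"], out["lon"], places.work_lat, places.work_lon)
        at_work = np.nan_to_num(d_work, nan=np.inf) <= places.work_radius_m
        out.loc[at_work, "lat"] = places.home_lat
        out.loc[at_work, "lon"] = places.home_lon
    return out
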