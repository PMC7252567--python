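"""GPS-based microenvironment (ME) classification at 5-s cadence.

Each 5-s GPS sample is assigned one of seven microenvironments —
indoors/outdoors at home, work, other, plus in-vehicle — with a small
decision tree:

1. sustained speed above a threshold marks in-vehicle travel;
2. otherwise the place (home / work / other) is chosen by radius
   membership around the geocoded building centers, nearest first;
3. indoor versus outdoor at that place is decided by fix quality — a
   missing fix or a position dilution of precision (PDOP) above the
   threshold indicates attenuated satellite reception, i.e. indoors;
4. labels are smoothed by a majority vote over a short dwell window;
5. samples with no data inherit the previous label.

Every threshold is configurable on :class:`PlaceGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .core import DAY_START_HOUR, TICKS_PER_DAY, TICK_SECONDS

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


class ME7(IntEnum):
    """Seven microenvironments; integer codes index one-hot vectors."""

    IN_HOME = 0
    IN_WORK = 1
    IN_OTHER = 2
    IN_VEHICLE = 3
    OUT_HOME = 4
    OUT_WORK = 5
    OUT_OTHER = 6


class ME5(IntEnum):
    """Five-class view: the three outdoor MEs collapse to one."""

    IN_HOME = 0
    IN_WORK = 1
    IN_OTHER = 2
    IN_VEHICLE = 3
    OUTDOORS = 4


_ME7_TO_ME5 = np.array([ME5.IN_HOME, ME5.IN_WORK, ME5.IN_OTHER, ME5.IN_VEHICLE,
                        ME5.OUTDOORS, ME5.OUTDOORS, ME5.OUTDOORS], dtype=np.int8)

#: Weekend lag-day substitution: work labels move to home (indoor and outdoor).
_WEEKEND_SUBST = {ME7.IN_WORK: ME7.IN_HOME, ME7.OUT_WORK: ME7.OUT_HOME}


@dataclass(frozen=True)
class PlaceGeometry:
    """Geocoded home/work centers with classification thresholds.

    Buildings are radius-buffered points (``*_radius_m``); a polygon
    hook could replace them without touching the decision tree.
    """

    home_lat: float
    home_lon: float
    work_lat: Optional[float] = None
    work_lon: Optional[float] = None
    home_radius_m: float = 40.0
    work_radius_m: float = 40.0
    vehicle_speed_kmh: float = 10.0
    vehicle_sustain_s: float = 30.0
    pdop_threshold: float = 4.0
    dwell_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.home_radius_m <= 0 or self.work_radius_m <= 0:
            raise ValueError("place radii must be positive")
        for name in ("vehicle_speed_kmh", "vehicle_sustain_s", "pdop_threshold",
                     "dwell_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def has_work(self) -> bool:
        return self.work_lat is not None


class MicroenvSeries:
    """One-hot ME labels on the full 5-s grid of a modeled day.

    Stores integer codes; the one-hot representation is derived, so the
    one-per-tick invariant holds by construction.
    """

    def __init__(self, ticks: pd.DatetimeIndex, codes: np.ndarray, n_classes: int = 7):
        codes = np.asarray(codes, dtype=np.int8)
        if len(ticks) != codes.size:
            raise ValueError("ticks and codes length mismatch")
        if codes.size != TICKS_PER_DAY:
            raise ValueError(f"a modeled day has {TICKS_PER_DAY} ticks, got {codes.size}")
        if codes.min() < 0 or codes.max() >= n_classes:
            raise ValueError("label code out of range")
        self.ticks = ticks
        self.codes = codes
        self.n_classes = n_classes

    def one_hot(self) -> np.ndarray:
        """(n_ticks, n_classes) 0/1 indicator array; rows sum to 1."""
        out = np.zeros((self.codes.size, self.n_classes), dtype=np.int8)
        out[np.arange(self.codes.size), self.codes] = 1
        return out

    def time_by_me_minutes(self) -> np.ndarray:
        """Minutes spent in each class over the day (sums to 1440)."""
        counts = np.bincount(self.codes, minlength=self.n_classes)
        return counts * (TICK_SECONDS / 60.0)

    def fraction_agreement(self, other: "MicroenvSeries") -> float:
        return float(np.mean(self.codes == other.codes))


def day_ticks(day: Date, day_start_hour: int = DAY_START_HOUR) -> pd.DatetimeIndex:
    """The 17,280 5-s timestamps of a modeled day."""
    start = pd.Timestamp(day) + pd.Timedelta(hours=day_start_hour)
    return pd.date_range(start, periods=TICKS_PER_DAY, freq=f"{TICK_SECONDS}s")


def _sustained_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only runs of True at least ``min_len`` long."""
    if mask.size == 0:
        return mask
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    out = np.zeros_like(mask)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out[s:e] = True
    return out


def _majority_smooth(codes: np.ndarray, n_classes: int, window: int) -> np.ndarray:
    """Majority vote over a centered window; current label wins ties."""
    if window <= 1:
        return codes
    n = codes.size
    onehot = np.zeros((n, n_classes), dtype=np.int32)
    onehot[np.arange(n), codes] = 1
    csum = np.vstack([np.zeros((1, n_classes), dtype=np.int32), np.cumsum(onehot, axis=0)])
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    counts = csum[hi] - csum[lo]
    # doubling counts and adding the current one-hot makes ties stick
    score = counts * 2 + onehot
    return np.argmax(score, axis=1).astype(np.int8)


def align_track_to_grid(track: pd.DataFrame, ticks: pd.DatetimeIndex) -> pd.DataFrame:
    """Snap GPS samples onto the day's 5-s grid.

    Sample timestamps are floored to the grid cadence; the last sample
    wins within a slot.  Slots with no sample have all-NaN fields.
    Positions of invalid fixes and empty slots are carried forward from
    the previous fix (a leading gap back-fills from the first fix).
    """
    if track.empty:
        raise ValueError("empty GPS track")
    t = track.copy()
    t["slot"] = t["timestamp"].dt.floor(f"{TICK_SECONDS}s")
    t = t[(t["slot"] >= ticks[0]) & (t["slot"] <= ticks[-1])]
    if t.empty:
        raise ValueError("GPS track does not overlap the modeled day window")
    t = t.drop_duplicates(subset="slot", keep="last").set_index("slot")
    g = t.reindex(ticks)

    # use any reported position (a logger may echo the last known one);
    # truly missing positions carry forward, a leading gap back-fills
    valid = g["valid"].fillna(False).to_numpy(dtype=bool)
    lat = pd.Series(g["lat"].to_numpy(dtype=float)).ffill().bfill().to_numpy()
    lon = pd.Series(g["lon"].to_numpy(dtype=float)).ffill().bfill().to_numpy()
    if np.isnan(lat).any():
        raise ValueError("track has no positioned sample at all")

    return pd.DataFrame(
        {
            "lat": lat,
            "lon": lon,
            "speed_kmh": g["speed_kmh"].to_numpy(dtype=float),
            "pdop": g["pdop"].to_numpy(dtype=float),
            "valid": valid,
            "observed": g["timestamp"].notna().to_numpy(),
        },
        index=ticks,
    )


def classify_me(track: pd.DataFrame, places: PlaceGeometry,
                day: Optional[Date] = None,
                day_start_hour: int = DAY_START_HOUR) -> MicroenvSeries:
    """Classify a day's GPS track into the seven microenvironments.

    ``track`` is a DataFrame with columns timestamp, lat, lon,
    speed_kmh, nsat, pdop, valid.  ``day`` defaults to the date of the
    first sample (shifted so the window starts at ``day_start_hour``).
    """
    if track.empty:
        raise ValueError("empty GPS track")
    if day is None:
        first = track["timestamp"].iloc[0]
        day = (first - pd.Timedelta(hours=day_start_hour)).date()
    ticks = day_ticks(day, day_start_hour)
    g = align_track_to_grid(track, ticks)

    speed = np.nan_to_num(g["speed_kmh"].to_numpy(), nan=0.0)
    fast = speed > places.vehicle_speed_kmh
    min_run = max(1, int(round(places.vehicle_sustain_s / TICK_SECONDS)))
    vehicle = _sustained_runs(fast, min_run)

    d_home = haversine_m(g["lat"], g["lon"], places.home_lat, places.home_lon)
    if places.has_work:
        d_work = haversine_m(g["lat"], g["lon"], places.work_lat, places.work_lon)
    else:
        d_work = np.full_like(d_home, np.inf)
    at_home = d_home <= places.home_radius_m
    at_work = d_work <= places.work_radius_m
    # nearest wins when both radii contain the point
    home_wins = at_home & (~at_work | (d_home <= d_work))
    work_wins = at_work & ~home_wins

    poor_fix = (~g["valid"].to_numpy()) | (np.nan_to_num(g["pdop"].to_numpy(), nan=np.inf)
                                           > places.pdop_threshold)

    codes = np.full(TICKS_PER_DAY, ME7.OUT_OTHER, dtype=np.int8)
    codes[home_wins & poor_fix] = ME7.IN_HOME
    codes[home_wins & ~poor_fix] = ME7.OUT_HOME
    codes[work_wins & poor_fix] = ME7.IN_WORK
    codes[work_wins & ~poor_fix] = ME7.OUT_WORK
    other = ~(home_wins | work_wins)
    codes[other & poor_fix] = ME7.IN_OTHER
    codes[other & ~poor_fix] = ME7.OUT_OTHER
    codes[vehicle] = ME7.IN_VEHICLE

    window = max(1, int(round(places.dwell_window_s / TICK_SECONDS)))
    if window % 2 == 0:
        window += 1
    codes = _majority_smooth(codes, 7, window)

    # unobserved slots inherit the previous (then next, for a leading gap) label
    observed = g["observed"].to_numpy()
    if not observed.all():
        lbl = pd.Series(np.where(observed, codes, np.nan))
        codes = lbl.ffill().bfill().to_numpy().astype(np.int8)

    return MicroenvSeries(ticks, codes, n_classes=7)


def collapse_to_five(me7: MicroenvSeries) -> MicroenvSeries:
    """Collapse the three outdoor MEs into a single outdoors class."""
    if me7.n_classes != 7:
        raise ValueError("expected a 7-class series")
    return MicroenvSeries(me7.ticks, _ME7_TO_ME5[me7.codes], n_classes=5)


def lag_day_me(me_day: MicroenvSeries, lag_date: Date, is_weekend: bool,
               day_start_hour: int = DAY_START_HOUR) -> MicroenvSeries:
    """Impute a lag day's ME series by copying the observed day.

    On weekend lag days any work label becomes the corresponding home
    label (indoors at work -> indoors at home; likewise outdoors).
    """
    if me_day.n_classes != 7:
        raise ValueError("expected a 7-class series")
    codes = me_day.codes.copy()
    if is_weekend:
        for src, dst in _WEEKEND_SUBST.items():
            codes[codes == src] = dst
    return MicroenvSeries(day_ticks(lag_date, day_start_hour), codes, n_classes=7)
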