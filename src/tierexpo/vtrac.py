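"""Accelerometer-based physical activity and inhaled minute ventilation.

At every 5-s tick the 1-s activity counts of the past 60 s are summed
(counts per minute, cpm) and classified into one of four physical
activity levels (PAL) with device-specific cut-points.  Ticks spent
in-vehicle are forced to sedentary, since the accelerometer picks up
vehicle motion while the occupant sits still.  Minute ventilation (MV,
m3/min) is a normalized-minute-ventilation (NMV, L/min per kg body
weight) table lookup by PAL, age band and sex, scaled by body weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Union

import numpy as np
import pandas as pd

from .core import TICKS_PER_DAY, TICK_SECONDS, Participant, Sex
from .microtrac import ME7, MicroenvSeries


class PalLevel(IntEnum):
    """Physical activity intensity levels, ordered."""

    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2
    VIGOROUS = 3


#: cpm cut-points for hip-worn activity counters; boundaries belong to the upper class.
PAL_CPM_THRESHOLDS = (100.0, 1535.0, 3962.0)


def rolling_cpm(counts: np.ndarray, at_ticks: bool = True) -> np.ndarray:
    """Counts per minute at each 5-s tick: sum of 1-s counts over (t-60 s, t].

    ``counts`` holds the day's 86,400 1-s epochs.  The first 59 s of the
    day are padded with zeros, biasing the start of day toward
    sedentary.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size != TICKS_PER_DAY * TICK_SECONDS:
        raise ValueError(f"expected {TICKS_PER_DAY * TICK_SECONDS} 1-s counts, "
                         f"got {counts.size}")
    if np.any(counts < 0):
        raise ValueError("activity counts must be nonnegative")
    csum = np.concatenate(([0], np.cumsum(counts)))
    t = (np.arange(1, TICKS_PER_DAY + 1) * TICK_SECONDS) if at_ticks \
        else np.arange(1, counts.size + 1)
    lo = np.maximum(t - 60, 0)
    return (csum[t] - csum[lo]).astype(float)


def classify_pal(cpm: Union[float, np.ndarray]) -> Union[PalLevel, np.ndarray]:
    """PAL from counts/min with the printed cut-points (100, 1535, 3962)."""
    arr = np.asarray(cpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cpm must be nonnegative")
    codes = np.digitize(arr, PAL_CPM_THRESHOLDS).astype(np.int8)
    if arr.ndim == 0:
        return PalLevel(int(codes))
    return codes


def vehicle_override(pal: Union[PalLevel, np.ndarray],
                     me: Union[ME7, np.ndarray]) -> Union[PalLevel, np.ndarray]:
    """Force sedentary whenever the time-matched ME is in-vehicle."""
    if np.isscalar(pal) or isinstance(pal, PalLevel):
        return PalLevel.SEDENTARY if me == ME7.IN_VEHICLE else pal
    pal = np.asarray(pal).copy()
    pal[np.asarray(me) == ME7.IN_VEHICLE] = PalLevel.SEDENTARY
    return pal


@dataclass(frozen=True)
class NmvTable:
    """Normalized minute ventilation (L/min/kg) by PAL, age band and sex.

    Backed by a tidy DataFrame with columns pal, age_lo, age_hi, sex,
    nmv_lpm_per_kg; age bands are half-open [age_lo, age_hi).  The table
    must be total over 4 PAL x bands x 2 sexes and nondecreasing in PAL
    within each (age band, sex) cell.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pal", "age_lo", "age_hi", "sex", "nmv_lpm_per_kg"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"NMV table needs columns {sorted(required)}")
        if (self.table["nmv_lpm_per_kg"] <= 0).any():
            raise ValueError("NMV values must be positive")
        for (lo, hi, sex), grp in self.table.groupby(["age_lo", "age_hi", "sex"]):
            g = grp.sort_values("pal")
            if len(g) != len(PalLevel):
                raise ValueError(f"cell age [{lo},{hi}) sex={sex} does not cover all PAL")
            if not g["nmv_lpm_per_kg"].is_monotonic_increasing:
                raise ValueError(f"NMV not nondecreasing in PAL for age [{lo},{hi}) sex={sex}")

    def lookup(self, pal: PalLevel, age: float, sex: Sex) -> float:
        """NMV (L/min/kg) for one (PAL, age, sex); raises naming a missing cell."""
        m = self.table[(self.table["pal"] == int(pal))
                       & (self.table["age_lo"] <= age) & (age < self.table["age_hi"])
                       & (self.table["sex"] == sex.value)]
        if m.empty:
            raise KeyError(f"no NMV entry for pal={PalLevel(pal).name}, age={age}, "
                           f"sex={sex.value}")
        return float(m["nmv_lpm_per_kg"].iloc[0])

    def lookup_vector(self, age: float, sex: Sex) -> np.ndarray:
        """NMV for all four PAL of one (age, sex), indexed by PAL code."""
        return np.array([self.lookup(PalLevel(p), age, sex) for p in range(4)])


#: Age band edges (years) for the 14-category NMV table.
NMV_AGE_EDGES = [0, 1, 3, 6, 11, 16, 21, 31, 41, 51, 61, 71, 81, 91, 120]

# Synthetic placeholder medians (L/min/kg) for a reference adult; the
# published NMV medians are not reproduced here, so analyses that need
# the real values must load them from CSV via NmvTable.
_BASE_NMV = {PalLevel.SEDENTARY: 0.10, PalLevel.LIGHT: 0.20,
             PalLevel.MODERATE: 0.32, PalLevel.VIGOROUS: 0.55}
# Per-kg ventilation is higher in children and declines mildly with age.
_AGE_FACTOR = [2.4, 2.2, 1.9, 1.6, 1.35, 1.15, 1.05, 1.0, 0.97, 0.94, 0.90, 0.86, 0.82, 0.78]
_SEX_FACTOR = {Sex.MALE: 1.00, Sex.FEMALE: 1.04}


def default_nmv_table() -> NmvTable:
    """Synthetic default NMV table: 4 PAL x 14 age bands x 2 sexes.

    Placeholder medians with realistic structure (nondecreasing in PAL,
    declining with adult age); intended for synthetic studies and as a
    template for a literature-derived CSV.
    """
    rows = []
    for i, (lo, hi) in enumerate(zip(NMV_AGE_EDGES[:-1], NMV_AGE_EDGES[1:])):
        for sex in Sex:
            for pal, base in _BASE_NMV.items():
                rows.append({"pal": int(pal), "age_lo": lo, "age_hi": hi,
                             "sex": sex.value,
                             "nmv_lpm_per_kg": round(base * _AGE_FACTOR[i]
                                                     * _SEX_FACTOR[sex], 4)})
    return NmvTable(pd.DataFrame(rows))


def minute_ventilation(pal: PalLevel, participant: Participant, nmv: NmvTable) -> float:
    """Minute ventilation in m3/min: NMV(pal, age, sex) * BW / 1000."""
    nmv_val = nmv.lookup(pal, participant.age, participant.sex)
    return nmv_val * participant.body_weight_kg / 1000.0


def minute_ventilation_series(pal_codes: np.ndarray, participant: Participant,
                              nmv: NmvTable) -> np.ndarray:
    """Vectorized MV (m3/min) for a day's 5-s PAL codes."""
    vec = nmv.lookup_vector(participant.age, participant.sex)
    return vec[np.asarray(pal_codes, dtype=np.int64)] * participant.body_weight_kg / 1000.0


def pal_series(counts: np.ndarray, me7: MicroenvSeries) -> np.ndarray:
    """Day pipeline: rolling cpm -> PAL -> in-vehicle override, at 5-s ticks."""
    cpm = rolling_cpm(counts, at_ticks=True)
    pal = classify_pal(cpm)
    return vehicle_override(pal, me7.codes)
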