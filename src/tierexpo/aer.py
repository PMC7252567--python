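"""Hourly residential air exchange rate (AER) from an extended LBL model.

The model combines three airflows in quadrature and divides by building
volume:

* leakage through unintentional envelope openings, driven by the stack
  effect (indoor-outdoor temperature difference) and wind,
* natural ventilation through open windows/doors, modeled as orifice
  flow through the reported openable area, and
* mechanical ventilation from window fans at their rated flow.

Stack and wind coefficients default from small built-in lookups keyed by
number of stories and wind-shielding class (classic LBL convention,
converted to SI); both can be set explicitly on :class:`HomeModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import DAY_START_HOUR

# Stack coefficient k_s ((m/s)^2 per K) by number of stories.
STACK_COEFF_BY_STORIES = {1: 0.0145, 2: 0.0290, 3: 0.0435}

# Wind coefficient k_w (dimensionless, applied to U^2) by stories and
# shielding class 1 (exposed) .. 5 (well shielded).
WIND_COEFF_BY_STORIES_SHIELDING = {
    1: {1: 0.0319, 2: 0.0246, 3: 0.0174, 4: 0.0104, 5: 0.0032},
    2: {1: 0.0420, 2: 0.0325, 3: 0.0231, 4: 0.0137, 5: 0.0042},
    3: {1: 0.0494, 2: 0.0382, 3: 0.0271, 4: 0.0161, 5: 0.0049},
}

#: Orifice discharge coefficient for flow through open windows and doors.
DISCHARGE_COEFF = 0.6


@dataclass(frozen=True)
class HomeModel:
    """Building characteristics that drive the air exchange rate.

    ``a_leak_m2`` is the effective leakage area, ``volume_m3`` the
    conditioned volume, ``openable_area_m2`` the total window/door area
    available when the occupant reports them open, and ``fan_flow_m3h``
    the rated window-fan flow.  ``stack_coeff``/``wind_coeff`` override
    the story/shielding lookups when given.
    """

    id: str
    a_leak_m2: float
    volume_m3: float
    openable_area_m2: float = 1.0
    fan_flow_m3h: float = 1000.0
    stories: int = 1
    shielding_class: int = 3
    stack_coeff: Optional[float] = None
    wind_coeff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a_leak_m2 <= 0 or self.volume_m3 <= 0:
            raise ValueError("leakage area and volume must be positive")
        if self.openable_area_m2 < 0 or self.fan_flow_m3h < 0:
            raise ValueError("openable area and fan flow must be nonnegative")
        if self.stories not in STACK_COEFF_BY_STORIES:
            raise ValueError(f"stories must be one of {sorted(STACK_COEFF_BY_STORIES)}")
        if self.shielding_class not in range(1, 6):
            raise ValueError("shielding_class must be in 1..5")
        if self.stack_coeff is not None and self.stack_coeff < 0:
            raise ValueError("stack_coeff must be >= 0")
        if self.wind_coeff is not None and self.wind_coeff < 0:
            raise ValueError("wind_coeff must be >= 0")

    @property
    def k_s(self) -> float:
        if self.stack_coeff is not None:
            return self.stack_coeff
        return STACK_COEFF_BY_STORIES[self.stories]

    @property
    def k_w(self) -> float:
        if self.wind_coeff is not None:
            return self.wind_coeff
        return WIND_COEFF_BY_STORIES_SHIELDING[self.stories][self.shielding_class]


@dataclass(frozen=True)
class QuestionnaireDay:
    """One home-day of occupant behavior from the daily questionnaire.

    ``imputed`` marks lag-day records copied from the clinic day.
    """

    date: Date
    t_in_c: float
    windows_open: bool
    doors_open: bool
    fan_on: bool
    imputed: bool = False

    def for_lag_day(self, lag_date: Date) -> "QuestionnaireDay":
        """Copy of this record re-dated to a lag day, flagged imputed."""
        return QuestionnaireDay(
            date=lag_date,
            t_in_c=self.t_in_c,
            windows_open=self.windows_open,
            doors_open=self.doors_open,
            fan_on=self.fan_on,
            imputed=True,
        )


class WeatherGapError(ValueError):
    """Raised when the weather table misses hours of a modeled window."""

    def __init__(self, missing: Sequence[pd.Timestamp]):
        self.missing = list(missing)
        super().__init__(f"weather table is missing {len(self.missing)} hour(s): "
                         f"{', '.join(str(t) for t in self.missing[:5])}"
                         + ("..." if len(self.missing) > 5 else ""))


ArrayLike = Union[float, np.ndarray]


def leakage_flow(home: HomeModel, t_in_c: ArrayLike, t_out_c: ArrayLike,
                 wind_mps: ArrayLike) -> ArrayLike:
    """Envelope leakage airflow, m3/h.

    Q_leak = A_leak * sqrt(k_s*|T_in - T_out| + k_w*U^2), evaluated in
    m3/s and converted to m3/h.  Zero when both driving forces vanish.
    """
    dT = np.abs(np.asarray(t_in_c, dtype=float) - np.asarray(t_out_c, dtype=float))
    u = np.asarray(wind_mps, dtype=float)
    q_mps = home.a_leak_m2 * np.sqrt(home.k_s * dT + home.k_w * u**2)
    out = q_mps * 3600.0
    return float(out) if np.isscalar(t_in_c) and np.isscalar(t_out_c) and np.isscalar(wind_mps) else out


def natural_flow(home: HomeModel, t_in_c: ArrayLike, t_out_c: ArrayLike,
                 wind_mps: ArrayLike, open_flag: Union[bool, np.ndarray]) -> ArrayLike:
    """Natural-ventilation airflow through open windows/doors, m3/h.

    Orifice flow with discharge coefficient 0.6 through the openable
    area, driven by the same stack/wind velocity scale as leakage; zero
    when nothing is reported open.
    """
    dT = np.abs(np.asarray(t_in_c, dtype=float) - np.asarray(t_out_c, dtype=float))
    u = np.asarray(wind_mps, dtype=float)
    v = np.sqrt(home.k_s * dT + home.k_w * u**2)
    q = DISCHARGE_COEFF * home.openable_area_m2 * v * 3600.0
    return np.where(open_flag, q, 0.0)


def total_flow(q_leak: ArrayLike, q_nat: ArrayLike, q_mech: ArrayLike) -> ArrayLike:
    """Combine the three airflows in quadrature: sqrt(Ql^2 + Qn^2 + Qm^2)."""
    ql, qn, qm = (np.asarray(q, dtype=float) for q in (q_leak, q_nat, q_mech))
    if np.any(ql < 0) or np.any(qn < 0) or np.any(qm < 0):
        raise ValueError("airflows must be nonnegative")
    out = np.sqrt(ql**2 + qn**2 + qm**2)
    return float(out) if out.ndim == 0 else out


def day_window(day: Date, day_start_hour: int = DAY_START_HOUR) -> pd.DatetimeIndex:
    """The 24 hourly timestamps of a modeled day (day_start to day_start + 24 h)."""
    start = pd.Timestamp(day) + pd.Timedelta(hours=day_start_hour)
    return pd.date_range(start, periods=24, freq="h")


def hourly_aer(home: HomeModel, weather: pd.DataFrame, quest: QuestionnaireDay,
               day_start_hour: int = DAY_START_HOUR) -> pd.Series:
    """Hourly AER (1/h) for one home-day.

    ``weather`` is indexed by hourly timestamps with columns ``t_out_c``
    and ``wind_mps`` and must cover the 24-h window starting at
    ``day_start_hour`` on ``quest.date``.  Indoor temperature is held at
    the questionnaire value for the whole day.
    """
    hours = day_window(quest.date, day_start_hour)
    missing = hours.difference(weather.index)
    if len(missing) > 0:
        raise WeatherGapError(missing)
    wx = weather.loc[hours]
    t_out = wx["t_out_c"].to_numpy(dtype=float)
    wind = wx["wind_mps"].to_numpy(dtype=float)
    q_leak = leakage_flow(home, quest.t_in_c, t_out, wind)
    q_nat = natural_flow(home, quest.t_in_c, t_out, wind,
                         quest.windows_open or quest.doors_open)
    q_mech = home.fan_flow_m3h if quest.fan_on else 0.0
    aer = total_flow(q_leak, q_nat, np.full(24, q_mech)) / home.volume_m3
    return pd.Series(aer, index=hours, name="aer")
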