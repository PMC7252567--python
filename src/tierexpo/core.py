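"""Shared domain types: pollutants, components, participants, anthropometrics.

Units are contracts throughout the package: concentrations in ug/m3, air
exchange rates in 1/h, airflows in m3/h at the API boundary, minute
ventilation in m3/min, inhaled dose in ug per m2 of body surface area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from types import MappingProxyType
from typing import Mapping, Optional


class Pollutant(str, Enum):
    """The four ambient pollutants the exposure model covers."""

    PM25 = "PM25"
    EC = "EC"
    NOX = "NOX"
    CO = "CO"


class Component(str, Enum):
    """Source apportionment of every concentration and tier metric.

    ``total`` is always the sum of ``background`` and ``onroad``.
    """

    BACKGROUND = "background"
    ONROAD = "onroad"
    TOTAL = "total"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class PollutantParams:
    """Per-pollutant infiltration constants.

    Parameters
    ----------
    penetration
        Fraction of the ambient pollutant that crosses the building
        envelope with infiltrating air (P, dimensionless, 0 < P <= 1).
    removal_rate
        First-order indoor loss rate (k_r, 1/h, >= 0), covering
        deposition and reaction.
    f_inf_other_bldg
        Equilibrium infiltration factor applied indoors in buildings
        other than the participant's home (dimensionless).
    f_inf_vehicle
        Infiltration factor applied inside vehicles (dimensionless).
    """

    penetration: float
    removal_rate: float
    f_inf_other_bldg: float
    f_inf_vehicle: float

    def __post_init__(self) -> None:
        if not (0.0 < self.penetration <= 1.0):
            raise ValueError(f"penetration must be in (0, 1], got {self.penetration}")
        if not (self.removal_rate >= 0.0 and math.isfinite(self.removal_rate)):
            raise ValueError(f"removal_rate must be finite and >= 0, got {self.removal_rate}")
        for name in ("f_inf_other_bldg", "f_inf_vehicle"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


# Literature-derived constants adopted by the model: penetration and indoor
# removal for the home mass balance, plus single-factor infiltration for
# non-home buildings and vehicles.  Overridable from configuration only.
_DEFAULT_PARAMS: Mapping[Pollutant, PollutantParams] = MappingProxyType(
    {
        Pollutant.PM25: PollutantParams(0.84, 0.21, 0.64, 0.44),
        Pollutant.EC: PollutantParams(0.98, 0.29, 0.59, 0.44),
        Pollutant.NOX: PollutantParams(1.00, 0.5, 1.00, 0.80),
        Pollutant.CO: PollutantParams(1.00, 0.0, 1.00, 1.00),
    }
)


def default_pollutant_params() -> Mapping[Pollutant, PollutantParams]:
    """Return the immutable default parameter registry for all pollutants."""
    return _DEFAULT_PARAMS


def pollutant_params_from_config(
    overrides: Mapping[str, Mapping[str, float]],
) -> Mapping[Pollutant, PollutantParams]:
    """Build a parameter registry with per-pollutant config overrides.

    ``overrides`` maps pollutant names to dicts with any of the keys
    ``P``, ``kr``, ``f_inf_other_bldg``, ``f_inf_vehicle`` (the TOML
    ``[pollutants.<name>]`` section).  Unknown pollutants or keys raise.
    """
    key_map = {
        "P": "penetration",
        "kr": "removal_rate",
        "f_inf_other_bldg": "f_inf_other_bldg",
        "f_inf_vehicle": "f_inf_vehicle",
    }
    out = dict(_DEFAULT_PARAMS)
    for pname, section in overrides.items():
        try:
            pol = Pollutant(pname.upper() if pname.upper() in Pollutant.__members__ else pname)
        except ValueError as exc:
            raise ValueError(f"unknown pollutant in config: {pname!r}") from exc
        base = out[pol]
        kwargs = {
            "penetration": base.penetration,
            "removal_rate": base.removal_rate,
            "f_inf_other_bldg": base.f_inf_other_bldg,
            "f_inf_vehicle": base.f_inf_vehicle,
        }
        for k, v in section.items():
            if k not in key_map:
                raise ValueError(f"unknown pollutant parameter key: {k!r}")
            kwargs[key_map[k]] = float(v)
        out[pol] = PollutantParams(**kwargs)
    return MappingProxyType(out)


@dataclass(frozen=True)
class Participant:
    """Study participant with the anthropometrics the dose model needs.

    ``home_lat``/``home_lon`` (and the optional work location) are WGS84
    decimal degrees.  Height in cm, weight in kg, age in years.
    """

    id: str
    age: float
    sex: Sex
    body_height_cm: float
    body_weight_kg: float
    home_lat: float
    home_lon: float
    work_lat: Optional[float] = None
    work_lon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.body_height_cm <= 0 or self.body_weight_kg <= 0:
            raise ValueError("body height and weight must be positive")
        if self.age < 18:
            raise ValueError("participants are adults (age >= 18)")
        if (self.work_lat is None) != (self.work_lon is None):
            raise ValueError("work location must give both lat and lon or neither")

    @property
    def has_work(self) -> bool:
        return self.work_lat is not None

    @property
    def body_surface_area_m2(self) -> float:
        return body_surface_area(self.body_height_cm, self.body_weight_kg)


def body_surface_area(body_height_cm: float, body_weight_kg: float) -> float:
    """Body surface area (m2) from the DuBois power-law formula.

    BSA = 0.007184 * BH^0.725 * BW^0.425 with height in cm, weight in kg.
    Strictly increasing in both arguments.
    """
    if body_height_cm <= 0 or body_weight_kg <= 0:
        raise ValueError("body height and weight must be positive")
    return 0.007184 * body_height_cm**0.725 * body_weight_kg**0.425


# Cadence constants shared by the 5-s pipeline stages.
TICK_SECONDS = 5
TICKS_PER_DAY = 24 * 3600 // TICK_SECONDS  # 17,280
DAY_START_HOUR = 8  # 24-h metrics run 8 am to 8 am local time
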