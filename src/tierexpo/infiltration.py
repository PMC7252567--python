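"""Home indoor concentrations of ambient pollutants (Tier 2).

A single-compartment mass balance links indoor to outdoor air:

    dC_in/dt = AER * P * C_out - (AER + k_r) * C_in

with AER the hourly air exchange rate (1/h), P the envelope penetration
coefficient and k_r the first-order indoor removal rate (1/h).  With
outdoor concentration and AER piecewise-constant over each hour the
update has an exact exponential solution, which is what
:func:`step_indoor` applies; the hourly integrator is therefore
unconditionally stable and free of time-step error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PollutantParams


class SeriesAlignmentError(ValueError):
    """Raised when two hourly series do not share identical timestamps."""


def validate_hourly(series: pd.Series, name: str = "series") -> None:
    """Check the hourly-series contract: 1-h spacing, finite, nonnegative."""
    idx = series.index
    if len(idx) == 0:
        raise ValueError(f"{name} is empty")
    if len(idx) > 1:
        deltas = np.diff(idx.asi8)
        if not np.all(deltas == 3_600_000_000_000):
            raise ValueError(f"{name} timestamps must be strictly increasing at 1-h spacing")
    vals = series.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(vals < 0):
        raise ValueError(f"{name} contains negative values")


def steady_state_ratio(params: PollutantParams, aer: float) -> float:
    """Equilibrium indoor/outdoor ratio AER*P / (AER + k_r), in (0, P].

    Undefined when both AER and k_r are zero (the indoor concentration
    then just tracks its initial condition).
    """
    if aer < 0:
        raise ValueError("AER must be nonnegative")
    denom = aer + params.removal_rate
    if denom == 0.0:
        raise ValueError("steady-state ratio undefined for AER = 0 and k_r = 0")
    return aer * params.penetration / denom


def step_indoor(c_in: float, c_out: float, aer: float, params: PollutantParams,
                dt_h: float = 1.0) -> float:
    """Advance the indoor concentration by ``dt_h`` hours.

    Exact solution for constant ``c_out`` and ``aer`` over the step:
    ``c_ss + (c_in - c_ss) * exp(-(aer + k_r) * dt)``.  When the decay
    rate is zero the indoor concentration is unchanged.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    if c_in < 0 or c_out < 0 or aer < 0:
        raise ValueError("inputs must be nonnegative")
    rate = aer + params.removal_rate
    if rate == 0.0:
        return c_in
    c_ss = aer * params.penetration * c_out / rate
    return c_ss + (c_in - c_ss) * np.exp(-rate * dt_h)


def indoor_series(c_out: pd.Series, aer: pd.Series, params: PollutantParams) -> pd.Series:
    """Hourly indoor concentration series from outdoor series and AER.

    Both inputs must share identical hourly timestamps.  The initial
    condition is the first hour's steady state (spin-up convention); if
    that steady state is undefined (AER = k_r = 0) the first outdoor
    value scaled by P is used instead.
    """
    if not c_out.index.equals(aer.index):
        raise SeriesAlignmentError("outdoor and AER series timestamps differ")
    validate_hourly(c_out, "c_out")
    validate_hourly(aer, "aer")

    co = c_out.to_numpy(dtype=float)
    a = aer.to_numpy(dtype=float)
    rate = a + params.removal_rate
    out = np.empty_like(co)

    if rate[0] > 0:
        c = a[0] * params.penetration * co[0] / rate[0]
    else:
        c = params.penetration * co[0]
    decay = np.exp(-rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_ss = np.where(rate > 0, a * params.penetration * co / np.where(rate > 0, rate, 1.0), 0.0)
    for i in range(co.size):
        if rate[i] > 0:
            c = c_ss[i] + (c - c_ss[i]) * decay[i]
        # rate == 0: c unchanged over the hour
        out[i] = c
    return pd.Series(out, index=c_out.index, name="c_in_home")
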