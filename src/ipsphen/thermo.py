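"""Temperature transformation chain.

Gridded or station air temperatures are corrected in two affine steps —
open-land to forest-stand air temperature, then forest air to phloem (bark)
temperature — before the daily effective bark temperature is computed with a
piecewise development-rate function:

* linear branch ``BT - 8.3`` between the lower development threshold
  (8.3 degC) and the optimum (30.4 degC),
* a nonlinear exponential decay between the optimum and the upper
  development threshold (38.9 degC),
* zero at or outside both thresholds.

The function value drops by about 0.43 dd at the optimum (the linear branch
gives 22.1 dd, the exponential branch just above gives about 21.67 dd); the
discontinuity is kept as published, with no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeatherSeries",
    "ForestAirTemps",
    "BarkTemps",
    "DevFunctionParams",
    "forest_air_temps",
    "bark_temps",
    "effective_bark_temp",
    "effective_series",
]

# Affine correction coefficients (intercept, slope), fitted for spruce stands.
AT_MIN_COEF = (1.44, 0.82)
AT_MEAN_COEF = (0.50, 0.81)
AT_MAX_COEF = (1.03, 0.86)
BT_MIN_COEF = (0.56, 0.99)
BT_MEAN_COEF = (-0.48, 1.03)
BT_MAX_COEF = (0.03, 0.99)


@dataclass(frozen=True)
class DailyWeatherSeries:
    """Gap-free daily min/mean/max air temperatures for one site or cell.

    Invariants: dates strictly increasing by one day; ``i_min <= i_mean <=
    i_max`` on every day; all values finite.
    """

    dates: pd.DatetimeIndex
    i_min: np.ndarray
    i_mean: np.ndarray
    i_max: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "i_min", np.asarray(self.i_min, dtype=float))
        object.__setattr__(self, "i_mean", np.asarray(self.i_mean, dtype=float))
        object.__setattr__(self, "i_max", np.asarray(self.i_max, dtype=float))
        n = len(self.dates)
        if not (len(self.i_min) == len(self.i_mean) == len(self.i_max) == n):
            raise ValueError("temperature arrays and dates must have equal length")
        if n == 0:
            raise ValueError("empty weather series")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            bad = int(np.argmax(deltas != 1))
            raise ValueError(
                f"dates must be daily and gap-free; irregular step after "
                f"{self.dates[bad].date()}"
            )
        for name, arr in (("i_min", self.i_min), ("i_mean", self.i_mean), ("i_max", self.i_max)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.argmax(~np.isfinite(arr)))
                raise ValueError(f"non-finite {name} on {self.dates[bad].date()}")
        order = (self.i_min <= self.i_mean) & (self.i_mean <= self.i_max)
        if not np.all(order):
            bad = int(np.argmax(~order))
            raise ValueError(
                f"temperature ordering violated on {self.dates[bad].date()}: "
                f"min={self.i_min[bad]}, mean={self.i_mean[bad]}, max={self.i_max[bad]}"
            )

    def __len__(self) -> int:
        return len(self.dates)

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "DailyWeatherSeries":
        """Sub-series covering [start, end] inclusive; raises if not covered."""
        wanted = pd.date_range(start, end, freq="D")
        missing = wanted.difference(self.dates)
        if len(missing):
            shown = ", ".join(str(d.date()) for d in missing[:5])
            more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
            raise ValueError(f"weather series missing dates: {shown}{more}")
        sel = self.dates.get_indexer(wanted)
        return DailyWeatherSeries(wanted, self.i_min[sel], self.i_mean[sel], self.i_max[sel])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "i_min": self.i_min, "i_mean": self.i_mean, "i_max": self.i_max}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailyWeatherSeries":
        dates = pd.DatetimeIndex(pd.to_datetime(frame["date"]))
        return cls(dates, frame["i_min"].to_numpy(), frame["i_mean"].to_numpy(),
                   frame["i_max"].to_numpy())


@dataclass(frozen=True)
class ForestAirTemps:
    """Daily min/mean/max air temperature inside the forest stand (degC)."""

    at_min: np.ndarray
    at_mean: np.ndarray
    at_max: np.ndarray


@dataclass(frozen=True)
class BarkTemps:
    """Daily min/mean/max bark (phloem) temperature (degC)."""

    bt_min: np.ndarray
    bt_mean: np.ndarray
    bt_max: np.ndarray


@dataclass(frozen=True)
class DevFunctionParams:
    """Constants of the piecewise development-rate function.

    ``dt_l``, ``t_o`` and ``dt_u`` are the lower development threshold, the
    developmental optimum and the upper development threshold (degC);
    ``alpha``, ``beta``, ``gamma`` and ``t_max_nl`` parameterise the
    exponential branch above the optimum.
    """

    dt_l: float = 8.3
    t_o: float = 30.4
    dt_u: float = 38.9
    alpha: float = 0.02876507
    beta: float = 3.5922336
    gamma: float = 1.24657367
    t_max_nl: float = 40.9958913

    def __post_init__(self) -> None:
        if not (self.dt_l < self.t_o < self.dt_u < self.t_max_nl):
            raise ValueError("thresholds must satisfy dt_l < t_o < dt_u < t_max_nl")
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must be positive")


def forest_air_temps(w: DailyWeatherSeries) -> ForestAirTemps:
    """Correct open-land air temperatures to forest-stand air temperatures."""
    return ForestAirTemps(
        at_min=AT_MIN_COEF[0] + AT_MIN_COEF[1] * w.i_min,
        at_mean=AT_MEAN_COEF[0] + AT_MEAN_COEF[1] * w.i_mean,
        at_max=AT_MAX_COEF[0] + AT_MAX_COEF[1] * w.i_max,
    )


def bark_temps(at: ForestAirTemps) -> BarkTemps:
    """Estimate bark temperatures from forest air temperatures."""
    return BarkTemps(
        bt_min=BT_MIN_COEF[0] + BT_MIN_COEF[1] * at.at_min,
        bt_mean=BT_MEAN_COEF[0] + BT_MEAN_COEF[1] * at.at_mean,
        bt_max=BT_MAX_COEF[0] + BT_MAX_COEF[1] * at.at_max,
    )


def effective_bark_temp(bt: float, p: DevFunctionParams | None = None) -> float:
    """Daily effective bark temperature (degree-days) for one bark temperature.

    Zero at or below ``dt_l`` and at or above ``dt_u``; ``bt - dt_l`` on the
    linear branch (which owns ``bt == t_o``); the exponential expression on
    ``(t_o, dt_u)``, clamped at 0 from below against roundoff.
    """
    p = p or DevFunctionParams()
    if not np.isfinite(bt):
        raise ValueError(f"non-finite bark temperature: {bt}")
    if bt <= p.dt_l or bt >= p.dt_u:
        return 0.0
    if bt <= p.t_o:
        return bt - p.dt_l
    value = (p.t_o - p.dt_l) * (
        np.exp(p.alpha * bt)
        - np.exp(p.alpha * p.t_max_nl - (p.t_max_nl - bt) / p.beta)
        - p.gamma
    )
    return max(0.0, float(value))


def effective_series(bt: np.ndarray, p: DevFunctionParams | None = None) -> np.ndarray:
    """Vectorised effective bark temperature over a daily series."""
    p = p or DevFunctionParams()
    bt = np.asarray(bt, dtype=float)
    if not np.all(np.isfinite(bt)):
        bad = int(np.argmax(~np.isfinite(bt)))
        raise ValueError(f"non-finite bark temperature at position {bad}")
    linear = bt - p.dt_l
    with np.errstate(over="ignore"):
        nonlinear = (p.t_o - p.dt_l) * (
            np.exp(p.alpha * bt)
            - np.exp(p.alpha * p.t_max_nl - (p.t_max_nl - bt) / p.beta)
            - p.gamma
        )
    out = np.where(bt <= p.t_o, linear, np.maximum(0.0, nonlinear))
    out[(bt <= p.dt_l) | (bt >= p.dt_u)] = 0.0
    return out
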