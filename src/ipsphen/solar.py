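"""Astronomical day length.

The brood-initiation rules use photoperiod as a diapause gate: no new filial
generation or sister brood is started once the day shortens below a threshold
(14.5 h by default).  This module supplies the day-length series that gate
consumes, using the Cooper declination approximation and the standard
sunrise-hour-angle formula with the geometric sun centre on the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SolarContext", "solar_declination", "day_length", "day_length_series"]

#: Obliquity-amplitude of the declination cycle, degrees.
DECLINATION_AMPLITUDE = 23.44


@dataclass(frozen=True)
class SolarContext:
    """Latitude and day of year for a day-length query.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    day_of_year : int
        1-based day of the calendar year, in [1, 366].
    """

    latitude: float
    day_of_year: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not 1 <= int(self.day_of_year) <= 366:
            raise ValueError(f"day_of_year {self.day_of_year} outside [1, 366]")


def solar_declination(day_of_year: int) -> float:
    """Solar declination in degrees for a day of year (Cooper formula).

    delta = 23.44 * sin(2*pi*(284 + n)/365).  The 365-day denominator is an
    accepted approximation; the error in day length is far below 0.1 h.
    """
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError(f"day_of_year {day_of_year} outside [1, 366]")
    return DECLINATION_AMPLITUDE * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)


def day_length(latitude: float, day_of_year: int, horizon_angle: float = 0.0) -> float:
    """Day length in hours for a latitude and day of year.

    Uses the sunrise hour angle cos(w0) = (sin(h0) - sin(phi) sin(delta)) /
    (cos(phi) cos(delta)) with the horizon elevation ``h0`` (degrees) at 0 by
    default: geometric sun centre on the horizon, no atmospheric refraction.
    A small negative ``horizon_angle`` (e.g. -0.83) reproduces the civil
    sunrise/sunset convention if the diapause-gate crossing date needs tuning.

    The hour-angle argument is clamped to [-1, 1], so polar day returns 24 h
    and polar night 0 h.
    """
    ctx = SolarContext(latitude, day_of_year)
    delta = math.radians(solar_declination(ctx.day_of_year))
    phi = math.radians(ctx.latitude)
    denom = math.cos(phi) * math.cos(delta)
    if denom == 0.0:  # pole: sun circles the horizon; fall back to clamp
        x = math.inf if math.sin(phi) * math.sin(delta) < 0 else -math.inf
    else:
        x = (math.sin(math.radians(horizon_angle)) - math.sin(phi) * math.sin(delta)) / denom
    x = min(1.0, max(-1.0, x))
    return (2.0 / 15.0) * math.degrees(math.acos(x))


def day_length_series(
    latitude: float, dates: pd.DatetimeIndex, horizon_angle: float = 0.0
) -> pd.Series:
    """Day length (hours) for each date, indexed by date."""
    values = np.array(
        [day_length(latitude, int(d.dayofyear), horizon_angle) for d in dates], dtype=float
    )
    return pd.Series(values, index=dates, name="daylength")
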