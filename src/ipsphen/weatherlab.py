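"""Synthetic daily weather generator.

Emulates a gridded nowcasting product's daily min/mean/max air temperatures
with a seasonal sinusoid, a diurnal envelope and seeded stochastic noise.
The daily mean is

    i_mean(d) = annual_mean + annual_amplitude * cos(2*pi*(d - phase_day)/365) + eps_d

and the extremes are placed outside the diurnal envelope,

    i_max(d) = i_mean(d) + diurnal_range/2 + |eta_d|
    i_min(d) = i_mean(d) - diurnal_range/2 - |eta'_d|,

so the ordering min <= mean <= max holds by construction for any noise draw.
Defaults approximate a sub-Alpine Central European climate (annual mean
around 9.5 degC, seasonal amplitude 10 degC, peak in late July, 9 degC
diurnal range) — the kind of site where spruce bark beetle outbreaks occur.
Deliberately unrealistic: no day-to-day autocorrelation, no fronts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .thermo import DailyWeatherSeries

__all__ = ["ClimateSpec", "generate_series", "generate_grid"]


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of the synthetic climate.

    ``annual_mean`` (degC), ``annual_amplitude`` (degC, seasonal half-range),
    ``phase_day`` (day of year of the temperature peak), ``diurnal_range``
    (degC between min and max before noise), ``noise_sd`` (degC, for both the
    mean perturbation and the outward envelope noise), ``seed``, ``year``,
    and the site ``latitude`` (degrees north, used downstream for day length).
    """

    annual_mean: float = 9.5
    annual_amplitude: float = 10.0
    phase_day: int = 200
    diurnal_range: float = 9.0
    noise_sd: float = 2.0
    seed: int = 0
    year: int = 2019
    latitude: float = 46.37

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_series(spec: ClimateSpec) -> DailyWeatherSeries:
    """One full calendar year (1 Jan - 31 Dec) of synthetic daily weather.

    Deterministic for a given spec; with ``noise_sd = 0`` the series is a
    closed-form function of the spec.
    """
    dates = pd.date_range(
        pd.Timestamp(spec.year, 1, 1), pd.Timestamp(spec.year, 12, 31), freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    rng = np.random.default_rng(spec.seed)
    n = len(dates)
    eps = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else np.zeros(n)
    eta_hi = np.abs(rng.normal(0.0, spec.noise_sd, n)) if spec.noise_sd else np.zeros(n)
    eta_lo = np.abs(rng.normal(0.0, spec.noise_sd, n)) if spec.noise_sd else np.zeros(n)
    i_mean = (
        spec.annual_mean
        + spec.annual_amplitude * np.cos(2.0 * np.pi * (doy - spec.phase_day) / 365.0)
        + eps
    )
    i_max = i_mean + spec.diurnal_range / 2.0 + eta_hi
    i_min = i_mean - spec.diurnal_range / 2.0 - eta_lo
    return DailyWeatherSeries(dates, i_min, i_mean, i_max)


def generate_grid(
    spec: ClimateSpec,
    nx: int,
    ny: int,
    lapse: float = -0.5,
    mask_fraction: float = 0.0,
    x_origin: float = 14.0,
    y_origin: float = 46.5,
    cell_size: float = 0.01,
):
    """Synthetic gridded weather: per-cell series with a north-south gradient.

    Row ``r`` (counted from the top, i.e. from the northern edge southwards)
    gets ``annual_mean + lapse * (ny - 1 - r)`` so that a negative ``lapse``
    makes northern rows colder.  Each cell draws its own noise from the
    deterministic per-cell seed ``spec.seed + r*nx + c`` (so a 1x1 grid
    reproduces :func:`generate_series` exactly); ``mask_fraction`` of cells
    are marked as lacking host trees, drawn from a separate seeded stream.

    Returns an :class:`ipsphen.io.GridCube` with a north-up geotransform
    anchored at the top-left corner ``(x_origin, y_origin)``.
    """
    from .io import GridCube  # local import to avoid a cycle

    if nx < 1 or ny < 1:
        raise ValueError("grid must be at least 1x1")
    if not 0.0 <= mask_fraction <= 1.0:
        raise ValueError("mask_fraction must be in [0, 1]")
    dates = pd.date_range(
        pd.Timestamp(spec.year, 1, 1), pd.Timestamp(spec.year, 12, 31), freq="D"
    )
    nt = len(dates)
    tmin = np.empty((nt, ny, nx))
    tmean = np.empty((nt, ny, nx))
    tmax = np.empty((nt, ny, nx))
    for r in range(ny):
        offset = lapse * (ny - 1 - r)
        for c in range(nx):
            cell_spec = dc_replace(
                spec, annual_mean=spec.annual_mean + offset, seed=spec.seed + r * nx + c
            )
            s = generate_series(cell_spec)
            tmin[:, r, c] = s.i_min
            tmean[:, r, c] = s.i_mean
            tmax[:, r, c] = s.i_max
    mask_rng = np.random.default_rng(spec.seed + nx * ny)
    host_mask = mask_rng.random((ny, nx)) >= mask_fraction
    if mask_fraction >= 1.0:
        host_mask[:] = False
    return GridCube(
        dates=dates,
        tmin=tmin,
        tmean=tmean,
        tmax=tmax,
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_size,
        crs="EPSG:4326",
        host_mask=host_mask,
    )
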