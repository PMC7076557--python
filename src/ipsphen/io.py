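"""Readers, writers and the grid-scale simulation driver.

Point weather travels as CSV (columns ``date,i_min,i_mean,i_max``); gridded
temperatures as a NetCDF cube with variables ``tmin``/``tmean``/``tmax`` over
``(time, y, x)``; the host-species mask and all map outputs as ESRI
ASCII-grid text rasters.  Onset rasters encode day-of-year as integers with
-1 as the NoData sentinel (declared in the header of every written raster).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .engine import (
    BROOD_ORDER,
    ModelParameters,
    PhenologyResult,
    Scenario,
    simulate_point,
)
from .thermo import DailyWeatherSeries

__all__ = [
    "GridCube",
    "GridResult",
    "read_weather_csv",
    "write_weather_csv",
    "read_grid",
    "write_grid",
    "read_raster_ascii",
    "write_raster",
    "read_observations_csv",
    "simulate_grid",
    "load_params_file",
]

NODATA = -1.0


# ---------------------------------------------------------------------------
# point weather CSV

WEATHER_COLUMNS = ("date", "i_min", "i_mean", "i_max")


def read_weather_csv(path) -> DailyWeatherSeries:
    """Read and validate a daily weather CSV.

    Reports the first violated invariant precisely: a malformed or duplicate
    date, a gap in the calendar, or a min/mean/max ordering violation, each
    with the offending row (1-based, header = row 1).
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    dates = pd.to_datetime(frame["date"], errors="coerce")
    if dates.isna().any():
        row = int(dates.isna().idxmax())
        raise ValueError(f"{path}: unparseable date {frame['date'][row]!r} at row {row + 2}")
    dup = dates.duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise ValueError(f"{path}: duplicate date {dates[row].date()} at row {row + 2}")
    deltas = dates.diff().dt.days.iloc[1:]
    if ((deltas != 1).any()):
        row = int((deltas != 1).idxmax())
        raise ValueError(
            f"{path}: dates not consecutive at row {row + 2} "
            f"(missing day after {dates[row - 1].date()})"
        )
    bad = ~((frame["i_min"] <= frame["i_mean"]) & (frame["i_mean"] <= frame["i_max"]))
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: i_min <= i_mean <= i_max violated at row {row + 2}")
    return DailyWeatherSeries(
        pd.DatetimeIndex(dates),
        frame["i_min"].to_numpy(float),
        frame["i_mean"].to_numpy(float),
        frame["i_max"].to_numpy(float),
    )


def write_weather_csv(w: DailyWeatherSeries, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(WEATHER_COLUMNS) + "\n")
        # repr round-trips float64 exactly, so write -> read is the identity
        for d, lo, me, hi in zip(w.dates, w.i_min, w.i_mean, w.i_max):
            fh.write(
                f"{d.date().isoformat()},{float(lo)!r},{float(me)!r},{float(hi)!r}\n"
            )


# ---------------------------------------------------------------------------
# gridded cube


@dataclass
class GridCube:
    """Georeferenced stack of daily min/mean/max temperature fields.

    North-up raster: ``(x_origin, y_origin)`` is the top-left corner,
    ``cell_size`` the square cell edge in CRS units.  ``host_mask`` is True
    where host trees are present (cells to simulate).
    """

    dates: pd.DatetimeIndex
    tmin: np.ndarray  # (time, y, x)
    tmean: np.ndarray
    tmax: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "EPSG:4326"
    host_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.tmin.shape == self.tmean.shape == self.tmax.shape):
            raise ValueError("tmin/tmean/tmax must share a shape")
        if self.tmin.ndim != 3 or self.tmin.shape[0] != len(self.dates):
            raise ValueError("temperature stacks must be (time, y, x) matching dates")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("cube time axis must be daily and gap-free")
        if self.host_mask is None:
            self.host_mask = np.ones(self.shape, dtype=bool)
        if self.host_mask.shape != self.shape:
            raise ValueError("host_mask shape must match the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1], self.tmin.shape[2]

    def geotransform(self) -> tuple[float, float, float]:
        return (self.x_origin, self.y_origin, self.cell_size)

    def cell_latitude(self, row: int) -> float:
        """Latitude of a cell centre (geographic CRS, north-up)."""
        return self.y_origin - (row + 0.5) * self.cell_size

    def cell_series(self, row: int, col: int) -> DailyWeatherSeries:
        return DailyWeatherSeries(
            self.dates,
            self.tmin[:, row, col],
            self.tmean[:, row, col],
            self.tmax[:, row, col],
        )

    def to_dataset(self) -> xr.Dataset:
        ny, nx = self.shape
        xs = self.x_origin + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(ny) + 0.5) * self.cell_size
        ds = xr.Dataset(
            {
                "tmin": (("time", "y", "x"), self.tmin),
                "tmean": (("time", "y", "x"), self.tmean),
                "tmax": (("time", "y", "x"), self.tmax),
                "host_mask": (("y", "x"), self.host_mask.astype(np.int8)),
            },
            coords={"time": self.dates, "y": ys, "x": xs},
            attrs={
                "crs": self.crs,
                "x_origin": self.x_origin,
                "y_origin": self.y_origin,
                "cell_size": self.cell_size,
            },
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "GridCube":
        dates = pd.DatetimeIndex(pd.to_datetime(ds["time"].values))
        mask = ds["host_mask"].values.astype(bool) if "host_mask" in ds else None
        return cls(
            dates=dates,
            tmin=np.asarray(ds["tmin"].values, float),
            tmean=np.asarray(ds["tmean"].values, float),
            tmax=np.asarray(ds["tmax"].values, float),
            x_origin=float(ds.attrs["x_origin"]),
            y_origin=float(ds.attrs["y_origin"]),
            cell_size=float(ds.attrs["cell_size"]),
            crs=str(ds.attrs.get("crs", "EPSG:4326")),
            host_mask=mask,
        )


def write_grid(cube: GridCube, path) -> None:
    """Write a cube as NetCDF (classic format via the scipy backend)."""
    cube.to_dataset().to_netcdf(path, engine="scipy")


def read_grid(path, mask_path=None) -> GridCube:
    """Read a NetCDF cube; optionally replace the host mask from an ASCII
    raster, which must be aligned with the cube's geotransform."""
    with xr.open_dataset(path, engine="scipy") as ds:
        cube = GridCube.from_dataset(ds.load())
    if mask_path is not None:
        mask, transform = read_raster_ascii(mask_path)
        if mask.shape != cube.shape or not np.allclose(
            transform, cube.geotransform(), atol=1e-9
        ):
            raise ValueError(
                "mask raster is not aligned with the cube: "
                f"mask geotransform {tuple(transform)} shape {mask.shape}, "
                f"cube geotransform {cube.geotransform()} shape {cube.shape}"
            )
        cube.host_mask = mask > 0
    return cube


# ---------------------------------------------------------------------------
# ASCII-grid rasters


def write_raster(field: np.ndarray, path, x_origin: float, y_origin: float,
                 cell_size: float, nodata: float = NODATA) -> None:
    """Write a 2-D field as an ESRI ASCII grid (plain text)."""
    ny, nx = field.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {x_origin!r}\n")
        fh.write(f"yllcorner {y_origin - ny * cell_size!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in field:
            fh.write(
                " ".join(
                    repr(float(v)) if np.isfinite(v) else repr(float(nodata)) for v in row
                )
            )
            fh.write("\n")


def read_raster_ascii(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an ESRI ASCII grid; returns (array, (x_origin, y_origin, cell_size))
    with the origin converted back to the top-left corner.  NoData cells keep
    the sentinel value declared in the header."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows, dtype=float)
    ny = int(header["nrows"])
    if arr.shape != (ny, int(header["ncols"])):
        raise ValueError(f"{path}: data shape {arr.shape} disagrees with header")
    y_origin = header["yllcorner"] + ny * header["cellsize"]
    return arr, (header["xllcorner"], y_origin, header["cellsize"])


# ---------------------------------------------------------------------------
# observations CSV


def read_observations_csv(path):
    """Read onset observations: columns site,year,lat,swarming_date,
    infestation_date (ISO dates; empty cell = absent)."""
    from .calibrate import OnsetObservation

    frame = pd.read_csv(path, comment="#")
    obs = []
    for _, row in frame.iterrows():
        def _date(v):
            return None if pd.isna(v) or str(v).strip() == "" else pd.Timestamp(v)

        obs.append(
            OnsetObservation(
                site=str(row["site"]),
                year=int(row["year"]),
                latitude=float(row["lat"]),
                observed_swarming=_date(row.get("swarming_date")),
                observed_infestation=_date(row.get("infestation_date")),
            )
        )
    return obs


# ---------------------------------------------------------------------------
# grid-scale simulation


@dataclass
class GridResult:
    """Raster outputs of one scenario: onset day-of-year fields, per-brood
    final relative thermal sums, and generation counts.  Masked cells hold
    the NoData sentinel (-1)."""

    scenario: Scenario
    swarming_doy: np.ndarray
    infestation_doy: np.ndarray
    final_tsum: dict[str, np.ndarray]
    n_filial: np.ndarray
    n_sister: np.ndarray


def simulate_grid(
    cube: GridCube,
    p: ModelParameters | None = None,
    scenarios: tuple[Scenario, ...] = (Scenario.AVG,),
    latitude_override: float | None = None,
) -> dict[Scenario, GridResult]:
    """Run the point pipeline independently on every unmasked cell.

    Cell latitude comes from the geotransform at cell centres for a
    geographic CRS; a projected CRS requires ``latitude_override``.  Cells
    are independent — any execution order yields identical rasters — and
    each cell's values equal :func:`simulate_point` on its extracted series.
    """
    p = p or ModelParameters()
    if not cube.host_mask.any():
        raise ValueError("host mask is empty: no cell to simulate")
    geographic = cube.crs.upper() in {"EPSG:4326", "CRS:84", "WGS84"}
    if not geographic and latitude_override is None:
        raise ValueError(
            f"projected CRS {cube.crs!r} requires an explicit latitude_override"
        )
    ny, nx = cube.shape
    out: dict[Scenario, GridResult] = {}
    for s in scenarios:
        s = Scenario(s)
        swarm = np.full((ny, nx), NODATA)
        infest = np.full((ny, nx), NODATA)
        tsums = {b: np.full((ny, nx), NODATA) for b in BROOD_ORDER}
        nf = np.full((ny, nx), NODATA)
        ns = np.full((ny, nx), NODATA)
        for r in range(ny):
            lat = latitude_override if latitude_override is not None else cube.cell_latitude(r)
            for c in range(nx):
                if not cube.host_mask[r, c]:
                    continue
                res = simulate_point(cube.cell_series(r, c), lat, p, s)
                if res.swarming_onset is not None:
                    swarm[r, c] = res.swarming_onset.dayofyear
                if res.infestation_onset is not None:
                    infest[r, c] = res.infestation_onset.dayofyear
                for t in res.broods:
                    tsums[t.brood_id][r, c] = t.final_tsum
                nf[r, c] = res.n_filial
                ns[r, c] = res.n_sister
        out[s] = GridResult(s, swarm, infest, tsums, nf, ns)
    return out


# ---------------------------------------------------------------------------
# configuration


_INT_KEYS = {"max_filial", "max_sister"}
_DATE_KEYS = {"start_month_day", "end_month_day"}


def load_params_file(path, base: ModelParameters | None = None) -> ModelParameters:
    """Plain-text ``key = value`` overrides for :class:`ModelParameters`.

    Lines starting with ``#`` are comments.  Dates are given as ``MM-DD``
    (e.g. ``start_month_day = 03-07``); development-function constants use a
    ``dev.`` prefix (e.g. ``dev.dt_l = 8.3``).
    """
    from dataclasses import replace as dc_replace

    from .thermo import DevFunctionParams

    base = base or ModelParameters()
    overrides: dict[str, object] = {}
    dev_overrides: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("dev."):
                dev_overrides[key[4:]] = float(value)
            elif key in _DATE_KEYS:
                month, day = (int(v) for v in value.split("-"))
                overrides[key] = (month, day)
            elif key in _INT_KEYS:
                overrides[key] = int(value)
            elif key == "stage_bounds":
                overrides[key] = tuple(float(v) for v in value.split(","))
            else:
                overrides[key] = float(value)
    if dev_overrides:
        overrides["dev"] = dc_replace(base.dev, **dev_overrides)
    try:
        return dc_replace(base, **overrides)
    except TypeError as exc:
        raise ValueError(f"{path}: unknown parameter ({exc})") from exc


def params_to_dict(p: ModelParameters) -> dict:
    """JSON-serialisable dump of the full parameter set (for provenance)."""
    return {
        "swarm_dd": p.swarm_dd,
        "infest_dd": p.infest_dd,
        "flight_t": p.flight_t,
        "daylength_gate": p.daylength_gate,
        "k_total": p.k_total,
        "hibernation_min": p.hibernation_min,
        "start_month_day": list(p.start_month_day),
        "end_month_day": list(p.end_month_day),
        "max_filial": p.max_filial,
        "max_sister": p.max_sister,
        "stage_bounds": list(p.stage_bounds),
        "horizon_angle": p.horizon_angle,
        "dev": {
            "dt_l": p.dev.dt_l,
            "t_o": p.dev.t_o,
            "dt_u": p.dev.dt_u,
            "alpha": p.dev.alpha,
            "beta": p.dev.beta,
            "gamma": p.dev.gamma,
            "t_max_nl": p.dev.t_max_nl,
        },
    }


def write_provenance(path, p: ModelParameters, extra: dict | None = None) -> None:
    payload = {"parameters": params_to_dict(p)}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
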