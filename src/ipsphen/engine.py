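"""Daily stepwise phenology simulation.

The season runs from 7 March to 31 October.  Spring swarming and infestation
begin on the first day on which the running sum of max(0, I_max - 8.3)
reaches the respective degree-day threshold (53.0 dd for swarming, 155.6 dd
for infestation) *and* that day's raw maximum air temperature exceeds the
flight-activity threshold (14.5 degC).  Onset gates deliberately use the raw
gridded I_max, not the forest-corrected AT_max; development, by contrast,
runs on the corrected bark-temperature chain.

From the infestation day the first filial generation F1 accumulates effective
bark temperature relative to the total development requirement K = 557 dd.
Sister broods S_j start on the first day with Tsum_F1 > j - 0.5; the second
and third filial generations start at Tsum_F1 > 1 and Tsum_F1 > 2 — all three
conditions additionally gated by warm flight weather (I_max > 14.5 degC) and
long days (day length >= 14.5 h, the diapause gate).  The day-length gate
blocks only brood initiation; broods already started keep accumulating to the
end of the season.  A brood survives the winter, and counts toward annual
voltinism, when its end-of-season relative thermal sum reaches 0.6 (pupal
development complete).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar import day_length_series
from .thermo import (
    BarkTemps,
    DailyWeatherSeries,
    DevFunctionParams,
    bark_temps,
    effective_series,
    forest_air_temps,
)

__all__ = [
    "Scenario",
    "ModelParameters",
    "BroodTrack",
    "PhenologyResult",
    "STAGE_LABELS",
    "degree_day_accumulator",
    "detect_onset",
    "accumulate_brood",
    "schedule_filial",
    "schedule_sisters",
    "classify_stage",
    "classify_stage_series",
    "count_generations",
    "simulate_point",
    "simulate_scenarios",
]

STAGE_LABELS = ("egg", "larva", "pupa", "teneral adult", "emerged adult")

FILIAL_IDS = ("F1", "F2", "F3")
SISTER_IDS = ("S1", "S2", "S3")
#: canonical reporting order (onset thresholds 0, 0.5, 1, 1.5, 2 on Tsum_F1)
BROOD_ORDER = ("F1", "S1", "F2", "S2", "F3", "S3")


class Scenario(str, enum.Enum):
    """Which bark-temperature variant drives development."""

    MIN = "min"
    AVG = "avg"
    MAX = "max"

    def pick(self, bt: BarkTemps) -> np.ndarray:
        return {Scenario.MIN: bt.bt_min, Scenario.AVG: bt.bt_mean,
                Scenario.MAX: bt.bt_max}[self]


@dataclass(frozen=True)
class ModelParameters:
    """All tunable constants of the phenology model.

    Degree-day onset thresholds (``swarm_dd``, ``infest_dd``), the
    flight-activity air-temperature gate ``flight_t`` (degC), the diapause
    day-length gate ``daylength_gate`` (h), the total development requirement
    ``k_total`` (dd), the hibernation-survival threshold ``hibernation_min``
    (relative thermal sum), the simulation window as month-day pairs, the
    development-rate function constants, brood caps, and the relative-thermal-
    sum breakpoints separating egg / larva / pupa / teneral adult / emerged
    adult.
    """

    swarm_dd: float = 53.0
    infest_dd: float = 155.6
    flight_t: float = 14.5
    daylength_gate: float = 14.5
    k_total: float = 557.0
    hibernation_min: float = 0.6
    start_month_day: tuple[int, int] = (3, 7)
    end_month_day: tuple[int, int] = (10, 31)
    dev: DevFunctionParams = field(default_factory=DevFunctionParams)
    max_filial: int = 3
    max_sister: int = 3
    stage_bounds: tuple[float, ...] = (0.1, 0.5, 0.6, 1.0)
    horizon_angle: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.swarm_dd < self.infest_dd:
            raise ValueError("need 0 < swarm_dd < infest_dd")
        if self.flight_t <= self.dev.dt_l:
            raise ValueError("flight_t must exceed the lower development threshold")
        if not 0 < self.hibernation_min < 1:
            raise ValueError("hibernation_min must lie in (0, 1)")
        if self.k_total <= 0:
            raise ValueError("k_total must be positive")
        if not 1 <= self.max_filial <= len(FILIAL_IDS):
            raise ValueError("max_filial must be in [1, 3]")
        if not 0 <= self.max_sister <= len(SISTER_IDS):
            raise ValueError("max_sister must be in [0, 3]")
        bounds = tuple(self.stage_bounds)
        if list(bounds) != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("stage_bounds must be strictly increasing")
        if bounds[0] <= 0 or bounds[-1] > 1:
            raise ValueError("stage_bounds must lie in (0, 1]")
        start = self.start_month_day
        end = self.end_month_day
        if start >= end:
            raise ValueError("start date must precede end date within the year")

    def window(self, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Simulation window (inclusive) for a calendar year."""
        return (
            pd.Timestamp(year, *self.start_month_day),
            pd.Timestamp(year, *self.end_month_day),
        )


@dataclass(frozen=True)
class BroodTrack:
    """One brood's development record over the season."""

    brood_id: str
    onset_day: pd.Timestamp | None
    tsum: pd.Series  # relative thermal sum per day; 0 before onset
    final_tsum: float
    survives: bool
    stage: pd.Series  # stage label per day from onset; <NA> before onset


@dataclass(frozen=True)
class PhenologyResult:
    """Per-site outcome of one scenario run."""

    scenario: Scenario
    latitude: float
    dates: pd.DatetimeIndex
    swarming_onset: pd.Timestamp | None
    infestation_onset: pd.Timestamp | None
    broods: tuple[BroodTrack, ...]
    n_filial: int
    n_sister: int

    def brood(self, brood_id: str) -> BroodTrack | None:
        for track in self.broods:
            if track.brood_id == brood_id:
                return track
        return None

    def to_summary_frame(self) -> pd.DataFrame:
        """One row per brood: onset date, final relative thermal sum, survival."""
        rows = [
            {
                "scenario": self.scenario.value,
                "brood_id": t.brood_id,
                "onset": None if t.onset_day is None else t.onset_day.date().isoformat(),
                "final_tsum": t.final_tsum,
                "survives": t.survives,
            }
            for t in self.broods
        ]
        return pd.DataFrame(rows, columns=["scenario", "brood_id", "onset", "final_tsum",
                                           "survives"])

    def to_daily_frame(self) -> pd.DataFrame:
        """Long-form daily record: date, scenario, brood_id, tsum, stage."""
        parts = []
        for t in self.broods:
            parts.append(
                pd.DataFrame(
                    {
                        "date": self.dates,
                        "scenario": self.scenario.value,
                        "brood_id": t.brood_id,
                        "tsum": t.tsum.to_numpy(),
                        "stage": t.stage.to_numpy(),
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["date", "scenario", "brood_id", "tsum", "stage"])
        return pd.concat(parts, ignore_index=True)


def degree_day_accumulator(
    i_max: pd.Series,
    base: float,
    expected_start: pd.Timestamp | None = None,
) -> pd.Series:
    """Running sum of max(0, i_max - base) from the start of the series.

    Negative daily increments are truncated at zero (standard degree-day
    practice: a cold day contributes nothing but never erases accrued sum).
    """
    if expected_start is not None and i_max.index[0] != expected_start:
        raise ValueError(
            f"series starts at {i_max.index[0].date()}, expected {expected_start.date()}"
        )
    inc = np.maximum(0.0, i_max.to_numpy(dtype=float) - base)
    return pd.Series(np.cumsum(inc), index=i_max.index)


def _first_true(mask: np.ndarray, index: pd.DatetimeIndex) -> pd.Timestamp | None:
    hits = np.flatnonzero(mask)
    return index[hits[0]] if len(hits) else None


def detect_onset(
    i_max: pd.Series, dd_threshold: float, p: ModelParameters | None = None
) -> pd.Timestamp | None:
    """Earliest day on which the degree-day sum has reached ``dd_threshold``
    AND that same day's I_max exceeds the flight-activity gate; None if never.

    A threshold crossing on a cold (gate-failing) day does not trigger
    retroactively — both conditions must hold on the onset day itself.
    The series must start on the model's start date.
    """
    p = p or ModelParameters()
    start = pd.Timestamp(i_max.index[0].year, *p.start_month_day)
    cum = degree_day_accumulator(i_max, p.dev.dt_l, expected_start=start)
    mask = (cum.to_numpy() >= dd_threshold) & (i_max.to_numpy() > p.flight_t)
    return _first_true(mask, i_max.index)


def accumulate_brood(
    onset: pd.Timestamp, bteff: pd.Series, k: float
) -> pd.Series:
    """Relative thermal sum of a brood: cumulative BTeff / k from the onset
    day (inclusive) through each day; zero before onset; not capped at 1."""
    if onset not in bteff.index:
        raise ValueError(f"onset {onset.date()} outside the simulation window")
    values = bteff.to_numpy(dtype=float)
    start = int(bteff.index.get_loc(onset))
    out = np.zeros(len(values))
    out[start:] = np.cumsum(values[start:]) / k
    return pd.Series(out, index=bteff.index)


def _gated_onset(
    tsum_f1: pd.Series,
    threshold: float,
    i_max: pd.Series,
    daylength: pd.Series,
    p: ModelParameters,
) -> pd.Timestamp | None:
    mask = (
        (tsum_f1.to_numpy() > threshold)
        & (i_max.to_numpy() > p.flight_t)
        & (daylength.to_numpy() >= p.daylength_gate)
    )
    return _first_true(mask, tsum_f1.index)


def schedule_filial(
    tsum_f1: pd.Series,
    i_max: pd.Series,
    daylength: pd.Series,
    p: ModelParameters | None = None,
) -> dict[str, pd.Timestamp | None]:
    """Onsets of the second and third filial generations.

    F2 starts on the first day with Tsum_F1 > 1 (strict), F3 with
    Tsum_F1 > 2 — both thresholds read on the *first* generation's thermal
    sum — subject to the flight-temperature and day-length gates.
    """
    p = p or ModelParameters()
    thresholds = {"F2": 1.0, "F3": 2.0}
    out: dict[str, pd.Timestamp | None] = {}
    for brood_id in FILIAL_IDS[1 : p.max_filial]:
        out[brood_id] = _gated_onset(tsum_f1, thresholds[brood_id], i_max, daylength, p)
    return out


def schedule_sisters(
    tsum_f1: pd.Series,
    i_max: pd.Series,
    daylength: pd.Series,
    p: ModelParameters | None = None,
) -> dict[str, pd.Timestamp | None]:
    """Onsets of sister broods: S_j starts at Tsum_F1 > j - 0.5 (strict),
    under the same flight and day-length gates."""
    p = p or ModelParameters()
    out: dict[str, pd.Timestamp | None] = {}
    for j in range(1, p.max_sister + 1):
        out[f"S{j}"] = _gated_onset(tsum_f1, j - 0.5, i_max, daylength, p)
    return out


def classify_stage(rel_tsum: float, bounds: tuple[float, ...] = (0.1, 0.5, 0.6, 1.0)) -> str:
    """Developmental stage for a relative thermal sum.

    Half-open intervals with the lower bound owned by the later stage:
    egg [0, 0.1), larva [0.1, 0.5), pupa [0.5, 0.6), teneral adult [0.6, 1.0),
    emerged adult at or above 1.0.
    """
    if rel_tsum < 0:
        raise ValueError(f"relative thermal sum must be >= 0, got {rel_tsum}")
    idx = int(np.searchsorted(np.asarray(bounds), rel_tsum, side="right"))
    return STAGE_LABELS[idx]


def classify_stage_series(
    tsum: pd.Series, onset: pd.Timestamp | None, bounds: tuple[float, ...] = (0.1, 0.5, 0.6, 1.0)
) -> pd.Series:
    """Stage label per day from the onset day onward; <NA> before onset."""
    labels = pd.Series(pd.NA, index=tsum.index, dtype="object")
    if onset is None:
        return labels
    idx = np.searchsorted(np.asarray(bounds), tsum.to_numpy(dtype=float), side="right")
    active = tsum.index >= onset
    labels[active] = np.asarray(STAGE_LABELS, dtype=object)[idx[active]]
    return labels


def count_generations(
    broods: tuple[BroodTrack, ...] | list[BroodTrack], p: ModelParameters | None = None
) -> tuple[int, int]:
    """Counts of filial and sister broods that reach the hibernation
    threshold (final relative thermal sum >= 0.6) by the end of the season.
    Initiated broods below the threshold are ignored."""
    p = p or ModelParameters()
    n_filial = sum(
        1
        for t in broods
        if t.brood_id.startswith("F") and t.onset_day is not None
        and t.final_tsum >= p.hibernation_min
    )
    n_sister = sum(
        1
        for t in broods
        if t.brood_id.startswith("S") and t.onset_day is not None
        and t.final_tsum >= p.hibernation_min
    )
    return n_filial, n_sister


def _make_track(
    brood_id: str,
    onset: pd.Timestamp | None,
    bteff: pd.Series,
    p: ModelParameters,
) -> BroodTrack:
    if onset is None:
        zeros = pd.Series(0.0, index=bteff.index)
        return BroodTrack(brood_id, None, zeros, 0.0, False,
                          classify_stage_series(zeros, None, p.stage_bounds))
    tsum = accumulate_brood(onset, bteff, p.k_total)
    final = float(tsum.iloc[-1])
    return BroodTrack(
        brood_id,
        onset,
        tsum,
        final,
        final >= p.hibernation_min,
        classify_stage_series(tsum, onset, p.stage_bounds),
    )


def simulate_point(
    w: DailyWeatherSeries,
    latitude: float,
    p: ModelParameters | None = None,
    scenario: Scenario = Scenario.AVG,
) -> PhenologyResult:
    """Run the full phenology chain for one site and one scenario.

    The weather series must cover the simulation window of its year; extra
    days outside the window are ignored.  The run is fully deterministic.
    """
    p = p or ModelParameters()
    scenario = Scenario(scenario)
    year = int(w.dates[0].year)
    start, end = p.window(year)
    sw = w.slice(start, end)

    bt = bark_temps(forest_air_temps(sw))
    bteff = pd.Series(effective_series(scenario.pick(bt), p.dev), index=sw.dates)
    i_max = pd.Series(sw.i_max, index=sw.dates)
    daylength = day_length_series(latitude, sw.dates, p.horizon_angle)

    swarming = detect_onset(i_max, p.swarm_dd, p)
    infestation = detect_onset(i_max, p.infest_dd, p)

    onsets: dict[str, pd.Timestamp | None] = {b: None for b in BROOD_ORDER}
    if infestation is not None:
        onsets["F1"] = infestation
        tsum_f1 = accumulate_brood(infestation, bteff, p.k_total)
        onsets.update(schedule_sisters(tsum_f1, i_max, daylength, p))
        onsets.update(schedule_filial(tsum_f1, i_max, daylength, p))

    broods = tuple(
        _make_track(brood_id, onsets.get(brood_id), bteff, p)
        for brood_id in BROOD_ORDER
        if _brood_enabled(brood_id, p)
    )
    n_filial, n_sister = count_generations(broods, p)
    return PhenologyResult(
        scenario=scenario,
        latitude=latitude,
        dates=sw.dates,
        swarming_onset=swarming,
        infestation_onset=infestation,
        broods=broods,
        n_filial=n_filial,
        n_sister=n_sister,
    )


def _brood_enabled(brood_id: str, p: ModelParameters) -> bool:
    if brood_id.startswith("F"):
        return int(brood_id[1]) <= p.max_filial
    return int(brood_id[1]) <= p.max_sister


def simulate_scenarios(
    w: DailyWeatherSeries,
    latitude: float,
    p: ModelParameters | None = None,
    scenarios: tuple[Scenario, ...] = (Scenario.MIN, Scenario.AVG, Scenario.MAX),
) -> dict[Scenario, PhenologyResult]:
    """Convenience wrapper running several scenarios on the same weather."""
    return {Scenario(s): simulate_point(w, latitude, p, Scenario(s)) for s in scenarios}
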