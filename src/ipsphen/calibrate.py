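"""Spring start-date calibration.

The degree-day sums that trigger swarming and infestation are accumulated
from a fixed spring start date.  The appropriate start date is region
specific and is found by iteration: for every candidate calendar day, onset
detection is re-run for every site-year of observations and the mean
absolute error (MAE, days) of predicted versus observed onset of swarming
and of infestation is computed; the chosen start date is the *latest*
candidate attaining the minimal combined MAE.

The combined objective is the unweighted mean of the swarming MAE and the
infestation MAE; site-years missing one observation contribute only to the
other term.  Site-years for which a candidate yields no prediction are
excluded from that candidate's MAE but counted; a candidate predicting fewer
than ``min_coverage`` of its pairs is disqualified, so a degenerate
"never predicts" candidate can never win.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .engine import ModelParameters, detect_onset
from .thermo import DailyWeatherSeries

__all__ = [
    "OnsetObservation",
    "MaeResult",
    "CalibrationResult",
    "mae_days",
    "candidate_grid",
    "calibrate_start_date",
]


@dataclass(frozen=True)
class OnsetObservation:
    """Observed onset dates for one site and year; either date may be absent."""

    site: str
    year: int
    latitude: float
    observed_swarming: pd.Timestamp | None = None
    observed_infestation: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.observed_swarming is None and self.observed_infestation is None:
            raise ValueError(f"{self.site}/{self.year}: at least one observed date required")


@dataclass(frozen=True)
class MaeResult:
    mae: float
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class CalibrationResult:
    """Chosen start date plus the full candidate table.

    ``chosen_start`` is a (month, day) pair; ``table`` has one row per
    candidate with columns candidate, mae_swarming, mae_infestation,
    mae_combined, n_pairs, n_excluded, coverage, qualified.
    """

    chosen_start: tuple[int, int]
    table: pd.DataFrame
    n_pairs: int


def mae_days(
    predicted: list[pd.Timestamp | None], observed: list[pd.Timestamp]
) -> MaeResult:
    """Mean absolute error in days over paired dates.

    Pairs with an absent prediction are excluded from the mean and counted
    in ``n_excluded``.  Raises if no valid pair remains.
    """
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must be paired")
    errs = [
        abs((pred - obs).days)
        for pred, obs in zip(predicted, observed)
        if pred is not None
    ]
    n_excluded = len(observed) - len(errs)
    if not errs:
        raise ValueError("no valid prediction/observation pairs")
    return MaeResult(float(np.mean(errs)), len(errs), n_excluded)


def candidate_grid(
    start: tuple[int, int] = (2, 1), end: tuple[int, int] = (4, 30)
) -> list[tuple[int, int]]:
    """Every calendar month-day from ``start`` through ``end`` (inclusive),
    step one day, on a non-leap reference year."""
    days = pd.date_range(pd.Timestamp(2001, *start), pd.Timestamp(2001, *end), freq="D")
    return [(d.month, d.day) for d in days]


def calibrate_start_date(
    observations: list[OnsetObservation],
    weather: dict[tuple[str, int], DailyWeatherSeries],
    candidates: list[tuple[int, int]] | None = None,
    p: ModelParameters | None = None,
    min_coverage: float = 0.9,
) -> CalibrationResult:
    """Find the start date minimising the combined onset MAE.

    For each candidate month-day, onset detection is re-run with the start
    date set to that candidate for every site-year; the returned table holds
    both per-onset MAEs and their unweighted mean, and ``chosen_start`` is
    the latest candidate among the qualified minima.
    """
    p = p or ModelParameters()
    candidates = candidates or candidate_grid()
    if not observations:
        raise ValueError("no observations supplied")
    for obs in observations:
        if (obs.site, obs.year) not in weather:
            raise ValueError(f"no weather series for site-year {obs.site}/{obs.year}")

    rows = []
    for cand in candidates:
        p_cand = dc_replace(p, start_month_day=cand)
        sw_pred, sw_obs, inf_pred, inf_obs = [], [], [], []
        for obs in observations:
            w = weather[(obs.site, obs.year)]
            start, end = p_cand.window(obs.year)
            try:
                ws = w.slice(start, end)
            except ValueError as exc:
                raise ValueError(
                    f"weather for {obs.site}/{obs.year} does not cover candidate "
                    f"{cand[0]:02d}-{cand[1]:02d}: {exc}"
                ) from exc
            i_max = pd.Series(ws.i_max, index=ws.dates)
            if obs.observed_swarming is not None:
                sw_pred.append(detect_onset(i_max, p_cand.swarm_dd, p_cand))
                sw_obs.append(obs.observed_swarming)
            if obs.observed_infestation is not None:
                inf_pred.append(detect_onset(i_max, p_cand.infest_dd, p_cand))
                inf_obs.append(obs.observed_infestation)

        terms, used, excluded = [], 0, 0
        for pred, ob in ((sw_pred, sw_obs), (inf_pred, inf_obs)):
            if not ob:
                continue
            try:
                r = mae_days(pred, ob)
            except ValueError:
                r = MaeResult(np.nan, 0, len(ob))
            terms.append(r.mae)
            used += r.n_used
            excluded += r.n_excluded
        n_pairs = used + excluded
        coverage = used / n_pairs if n_pairs else 0.0
        combined = float(np.mean(terms)) if terms else np.nan
        rows.append(
            {
                "candidate": f"{cand[0]:02d}-{cand[1]:02d}",
                "mae_swarming": terms[0] if sw_obs else np.nan,
                "mae_infestation": terms[-1] if inf_obs else np.nan,
                "mae_combined": combined,
                "n_pairs": n_pairs,
                "n_excluded": excluded,
                "coverage": coverage,
                "qualified": coverage >= min_coverage and np.isfinite(combined),
            }
        )
    table = pd.DataFrame(rows)
    qualified = table[table["qualified"]]
    if qualified.empty:
        raise ValueError("no candidate start date yields sufficient prediction coverage")
    best = qualified["mae_combined"].min()
    # latest candidate among the minima
    winners = qualified[qualified["mae_combined"] == best]
    chosen = winners.iloc[-1]["candidate"]
    month, day = (int(x) for x in chosen.split("-"))
    n_pairs = int(table["n_pairs"].max())
    return CalibrationResult((month, day), table, n_pairs)
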