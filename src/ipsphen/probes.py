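"""Behavioural verification probes.

Each probe recovers one of the model's printed constants purely from the
behaviour of the public simulation surface — by bisection on a constructed
input, or by scanning for a discontinuity — rather than by reading the
parameter back.  They serve as end-to-end checks that the constants are
actually wired through the temperature chain, the onset detector, the brood
scheduler and the generation counter.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .engine import (
    BroodTrack,
    ModelParameters,
    Scenario,
    count_generations,
    detect_onset,
    schedule_filial,
)
from .thermo import DevFunctionParams, effective_bark_temp

__all__ = [
    "bisect_boundary",
    "locate_lower_dev_threshold",
    "locate_upper_dev_threshold",
    "locate_swarming_dd_threshold",
    "locate_infestation_dd_threshold",
    "locate_flight_gate",
    "locate_daylength_gate",
    "locate_hibernation_threshold",
    "locate_branch_switch",
]


def bisect_boundary(predicate, lo: float, hi: float, tol: float) -> float:
    """Infimum of the set where ``predicate`` is True on [lo, hi].

    Requires predicate(lo) False and predicate(hi) True (a single upward
    boundary).  Returns the midpoint of the final bracket.
    """
    if predicate(lo):
        raise ValueError("predicate already true at the lower bound")
    if not predicate(hi):
        raise ValueError("predicate never true on the interval")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def locate_lower_dev_threshold(
    p: DevFunctionParams | None = None, tol: float = 1e-6
) -> float:
    """Bark temperature at which development first becomes positive (degC)."""
    p = p or DevFunctionParams()
    return bisect_boundary(lambda t: effective_bark_temp(t, p) > 0.0, 0.0, 20.0, tol)


def locate_upper_dev_threshold(
    p: DevFunctionParams | None = None, tol: float = 1e-6
) -> float:
    """Bark temperature at and above which development is forced to zero (degC)."""
    p = p or DevFunctionParams()
    return bisect_boundary(lambda t: effective_bark_temp(t, p) == 0.0, 31.0, 45.0, tol)


def _onset_probe_series(total_dd: float, p: ModelParameters, year: int = 2019):
    """Daily I_max series whose truncated degree-day sum reaches exactly
    ``total_dd`` on its last day, with the flight gate open every day.

    Built from k filler days at 14.6 degC (6.3 dd each) plus one final
    warmer day carrying the remainder, so the remainder stays above the
    flight gate."""
    day_dd = 14.6 - p.dev.dt_l  # 6.3 dd per filler day
    k = max(0, math.ceil((total_dd - 2 * day_dd) / day_dd))
    remainder = total_dd - k * day_dd
    values = [14.6] * k + [p.dev.dt_l + remainder]
    start = pd.Timestamp(year, *p.start_month_day)
    index = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=index)


def _dd_threshold_probe(threshold_attr: str, p: ModelParameters, tol: float) -> float:
    def declared(total_dd: float) -> bool:
        series = _onset_probe_series(total_dd, p)
        onset = detect_onset(series, getattr(p, threshold_attr), p)
        return onset is not None

    return bisect_boundary(declared, 20.0, 300.0, tol)


def locate_swarming_dd_threshold(
    p: ModelParameters | None = None, tol: float = 1e-4
) -> float:
    """Minimum cumulative sum of (I_max - 8.3) that triggers swarming (dd)."""
    return _dd_threshold_probe("swarm_dd", p or ModelParameters(), tol)


def locate_infestation_dd_threshold(
    p: ModelParameters | None = None, tol: float = 1e-4
) -> float:
    """Minimum cumulative sum of (I_max - 8.3) that triggers infestation (dd)."""
    return _dd_threshold_probe("infest_dd", p or ModelParameters(), tol)


def locate_flight_gate(p: ModelParameters | None = None, tol: float = 1e-6) -> float:
    """I_max below which swarming is never declared, whatever the sum (degC)."""
    p = p or ModelParameters()
    start, end = p.window(2019)
    index = pd.date_range(start, end, freq="D")

    def declared(t: float) -> bool:
        series = pd.Series(t, index=index)
        return detect_onset(series, p.swarm_dd, p) is not None

    return bisect_boundary(declared, 10.0, 20.0, tol)


def locate_daylength_gate(p: ModelParameters | None = None, tol: float = 1e-6) -> float:
    """Constant day length below which no second filial generation starts (h)."""
    p = p or ModelParameters()
    start, _ = p.window(2019)
    index = pd.date_range(start, periods=60, freq="D")
    # parent thermal sum climbing 0.1/day: exceeds 1 from day 11 onward
    tsum_f1 = pd.Series(0.1 * np.arange(1, len(index) + 1), index=index)
    i_max = pd.Series(20.0, index=index)

    def initiated(daylength: float) -> bool:
        dl = pd.Series(daylength, index=index)
        return schedule_filial(tsum_f1, i_max, dl, p)["F2"] is not None

    return bisect_boundary(initiated, 12.0, 16.0, tol)


def locate_hibernation_threshold(
    p: ModelParameters | None = None, tol: float = 1e-9
) -> float:
    """Minimum end-of-season relative thermal sum for a brood to count."""
    p = p or ModelParameters()
    start, _ = p.window(2019)
    index = pd.date_range(start, periods=10, freq="D")

    def counted(final_tsum: float) -> bool:
        tsum = pd.Series(np.linspace(0.0, final_tsum, len(index)), index=index)
        track = BroodTrack(
            brood_id="F1",
            onset_day=index[0],
            tsum=tsum,
            final_tsum=final_tsum,
            survives=final_tsum >= p.hibernation_min,
            stage=pd.Series(pd.NA, index=index, dtype="object"),
        )
        n_filial, _ = count_generations([track], p)
        return n_filial == 1

    return bisect_boundary(counted, 0.0, 1.0, tol)


def locate_branch_switch(
    p: DevFunctionParams | None = None, step: float = 1e-4
) -> float:
    """Temperature of the linear-to-nonlinear branch switch, found as the
    largest jump between adjacent evaluations on a fine scan of [9, 38] degC."""
    from .thermo import effective_series

    p = p or DevFunctionParams()
    grid = np.arange(9.0, 38.0 + step, step)
    values = effective_series(grid, p)
    jumps = np.abs(np.diff(values))
    i = int(np.argmax(jumps))
    return float(0.5 * (grid[i] + grid[i + 1]))
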