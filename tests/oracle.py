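"""Independent brute-force re-implementation of the daily phenology loop.

Used as the oracle against the vectorised engine: everything is recomputed
from scratch every day with plain Python arithmetic — the temperature chain
inline, cumulative sums re-derived by summation over all previous days, and
onset conditions re-checked daily.  Shares no code path with the engine
except the day-length helper.
"""

import math

import pandas as pd

from ipsphen.solar import day_length

BROODS = [("S1", 0.5), ("F2", 1.0), ("S2", 1.5), ("F3", 2.0), ("S3", 2.5)]


def _bteff(bt, p):
    d = p.dev
    if bt <= d.dt_l or bt >= d.dt_u:
        return 0.0
    if bt <= d.t_o:
        return bt - d.dt_l
    v = (d.t_o - d.dt_l) * (
        math.exp(d.alpha * bt)
        - math.exp(d.alpha * d.t_max_nl - (d.t_max_nl - bt) / d.beta)
        - d.gamma
    )
    return max(0.0, v)


def naive_simulate(w, latitude, p, scenario):
    """Returns (swarming, infestation, onsets dict, final tsums dict)."""
    year = int(w.dates[0].year)
    start = pd.Timestamp(year, *p.start_month_day)
    end = pd.Timestamp(year, *p.end_month_day)
    idx = [i for i, d in enumerate(w.dates) if start <= d <= end]
    dates = [w.dates[i] for i in idx]
    imax_raw = [float(w.i_max[i]) for i in idx]

    coef = {
        "min": ((1.44, 0.82), (0.56, 0.99), [float(w.i_min[i]) for i in idx]),
        "avg": ((0.50, 0.81), (-0.48, 1.03), [float(w.i_mean[i]) for i in idx]),
        "max": ((1.03, 0.86), (0.03, 0.99), [float(w.i_max[i]) for i in idx]),
    }[str(getattr(scenario, "value", scenario))]
    (a1, b1), (a2, b2), driver = coef
    bteff = [_bteff(a2 + b2 * (a1 + b1 * t), p) for t in driver]
    dl = [day_length(latitude, int(d.dayofyear), p.horizon_angle) for d in dates]

    swarming = infestation = None
    onsets = {}
    for i, d in enumerate(dates):
        cum = sum(max(0.0, imax_raw[j] - p.dev.dt_l) for j in range(i + 1))
        gate = imax_raw[i] > p.flight_t
        if swarming is None and gate and cum >= p.swarm_dd:
            swarming = d
        if infestation is None and gate and cum >= p.infest_dd:
            infestation = d
        if infestation is not None:
            i0 = dates.index(infestation)
            tsum_f1 = sum(bteff[j] for j in range(i0, i + 1)) / p.k_total
            for brood_id, threshold in BROODS:
                enabled = (
                    int(brood_id[1]) <= p.max_filial
                    if brood_id.startswith("F")
                    else int(brood_id[1]) <= p.max_sister
                )
                if (
                    enabled
                    and brood_id not in onsets
                    and tsum_f1 > threshold
                    and gate
                    and dl[i] >= p.daylength_gate
                ):
                    onsets[brood_id] = d

    if infestation is not None:
        onsets["F1"] = infestation
    finals = {}
    for brood_id, onset in onsets.items():
        i0 = dates.index(onset)
        finals[brood_id] = sum(bteff[j] for j in range(i0, len(dates))) / p.k_total
    return swarming, infestation, onsets, finals
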