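"""Onset detection, brood scheduling, stage classification, full runs."""

import numpy as np
import pandas as pd
import pytest

from conftest import window_series
from ipsphen import (
    ClimateSpec,
    ModelParameters,
    Scenario,
    accumulate_brood,
    classify_stage,
    count_generations,
    degree_day_accumulator,
    detect_onset,
    generate_series,
    schedule_filial,
    schedule_sisters,
    simulate_point,
    simulate_scenarios,
)
from ipsphen.engine import BroodTrack, classify_stage_series
from oracle import naive_simulate


class TestDegreeDayAccumulator:
    def test_constant_accumulation(self):
        s = window_series([18.3] * 10)
        cum = degree_day_accumulator(s, 8.3)
        np.testing.assert_allclose(cum.to_numpy(), 10.0 * np.arange(1, 11))

    def test_at_base_gives_zero(self):
        cum = degree_day_accumulator(window_series([8.3] * 5), 8.3)
        assert (cum == 0).all()

    def test_negative_increment_truncated(self):
        cum = degree_day_accumulator(window_series([5.0, 20.0]), 8.3)
        np.testing.assert_allclose(cum.to_numpy(), [0.0, 11.7])

    def test_start_date_validation(self):
        s = window_series([10.0] * 3, month=4, day=1)
        with pytest.raises(ValueError, match="expected 2019-03-07"):
            degree_day_accumulator(s, 8.3, expected_start=pd.Timestamp("2019-03-07"))


class TestOnsetDetection:
    def test_swarming_on_sixth_day(self, params):
        onset = detect_onset(window_series([18.3] * 30), params.swarm_dd, params)
        assert onset == pd.Timestamp("2019-03-12")  # cum 60 dd; day 5 has only 50

    def test_infestation_on_sixteenth_day(self, params):
        onset = detect_onset(window_series([18.3] * 30), params.infest_dd, params)
        assert onset == pd.Timestamp("2019-03-22")  # cum 160 dd

    def test_gate_failing_days_do_not_trigger_retroactively(self, params):
        # 10 cool days accumulate 50 dd but fail the 14.5 degC flight gate;
        # the first warm day completes both conditions simultaneously.
        onset = detect_onset(window_series([13.3] * 10 + [20.0]), params.swarm_dd, params)
        assert onset == pd.Timestamp("2019-03-17")

    def test_never_warm_enough_gives_absent(self, params):
        assert detect_onset(window_series([14.5] * 200), params.swarm_dd, params) is None


class TestBroodAccumulation:
    def test_hundred_days_at_557th_rate(self):
        bteff = window_series([5.57] * 100)
        tsum = accumulate_brood(bteff.index[0], bteff, 557.0)
        assert tsum.iloc[-1] == pytest.approx(1.0)

    def test_zero_bteff_stays_zero(self):
        bteff = window_series([0.0] * 20)
        tsum = accumulate_brood(bteff.index[3], bteff, 557.0)
        assert (tsum == 0).all()

    def test_onset_day_included(self):
        bteff = window_series([55.7] * 10)
        tsum = accumulate_brood(bteff.index[0], bteff, 557.0)
        assert tsum.iloc[0] == pytest.approx(0.1)

    def test_zero_before_onset_and_nondecreasing(self):
        bteff = window_series([3.0] * 30)
        onset = bteff.index[10]
        tsum = accumulate_brood(onset, bteff, 557.0)
        assert (tsum[tsum.index < onset] == 0).all()
        assert (tsum.diff().dropna() >= 0).all()

    def test_onset_outside_window_rejected(self):
        bteff = window_series([3.0] * 5)
        with pytest.raises(ValueError, match="outside"):
            accumulate_brood(pd.Timestamp("2019-06-01"), bteff, 557.0)


class TestBroodScheduling:
    """Constant BTeff = 55.7 gives Tsum_F1 = 0.1 per day: tie-breaks are exact."""

    @pytest.fixture()
    def open_gates(self):
        # exact decimal tenths (n/10.0), so ties at 0.5, 1.0, ... are exact
        tsum = window_series(np.arange(1, 41) / 10.0)
        i_max = window_series([20.0] * 40)
        daylength = window_series([15.0] * 40)
        return tsum, i_max, daylength

    def test_filial_strict_inequality_tie_break(self, open_gates, params):
        tsum, i_max, dl = open_gates
        onsets = schedule_filial(tsum, i_max, dl, params)
        assert onsets["F2"] == tsum.index[10]  # day 11: 1.1 > 1; day 10 is exactly 1.0
        assert onsets["F3"] == tsum.index[20]  # day 21: 2.1 > 2

    def test_sister_strict_inequality_tie_break(self, open_gates, params):
        tsum, i_max, dl = open_gates
        onsets = schedule_sisters(tsum, i_max, dl, params)
        assert onsets["S1"] == tsum.index[5]  # day 6: 0.6 > 0.5; day 5 is exactly 0.5
        assert onsets["S2"] == tsum.index[15]
        assert onsets["S3"] == tsum.index[25]

    def test_short_days_block_all_initiation(self, open_gates, params):
        tsum, i_max, _ = open_gates
        short = window_series([14.0] * 40)
        assert all(v is None for v in schedule_filial(tsum, i_max, short, params).values())
        assert all(v is None for v in schedule_sisters(tsum, i_max, short, params).values())

    def test_low_parent_tsum_blocks_sisters(self, params):
        tsum = window_series([0.01] * 40).cumsum()  # never exceeds 0.5
        i_max = window_series([20.0] * 40)
        dl = window_series([15.0] * 40)
        assert all(v is None for v in schedule_sisters(tsum, i_max, dl, params).values())


class TestStageClassification:
    @pytest.mark.parametrize(
        "tsum, stage",
        [
            (0.0, "egg"),
            (0.05, "egg"),
            (0.1, "larva"),  # lower bound owned by the later stage
            (0.49, "larva"),
            (0.5, "pupa"),
            (0.55, "pupa"),
            (0.6, "teneral adult"),
            (0.99, "teneral adult"),
            (1.0, "emerged adult"),
            (1.7, "emerged adult"),
        ],
    )
    def test_half_open_intervals(self, tsum, stage):
        assert classify_stage(tsum) == stage

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stage(-0.1)

    def test_series_is_na_before_onset(self):
        tsum = window_series([0.0] * 5 + [0.2] * 5)
        labels = classify_stage_series(tsum, tsum.index[5])
        assert labels.iloc[:5].isna().all()
        assert (labels.iloc[5:] == "larva").all()


class TestGenerationCounting:
    @staticmethod
    def track(brood_id, final, onset="2019-05-01"):
        idx = pd.date_range("2019-05-01", periods=3, freq="D")
        tsum = pd.Series([0, final / 2, final], index=idx)
        return BroodTrack(brood_id, pd.Timestamp(onset), tsum, final, final >= 0.6,
                          pd.Series(pd.NA, index=idx, dtype="object"))

    def test_hibernation_cutoff(self, params):
        broods = [self.track("F1", 1.2), self.track("F2", 0.7), self.track("F3", 0.3)]
        assert count_generations(broods, params) == (2, 0)

    def test_threshold_is_inclusive(self, params):
        assert count_generations([self.track("F1", 0.6)], params) == (1, 0)

    def test_sisters_counted_separately(self, params):
        broods = [self.track("F1", 1.0), self.track("S1", 0.8), self.track("S2", 0.2)]
        assert count_generations(broods, params) == (1, 1)

    def test_no_broods(self, params):
        assert count_generations([], params) == (0, 0)


class TestSimulatePoint:
    def test_worked_chronology(self, constant_weather, params):
        res = simulate_point(constant_weather, 46.37, params, Scenario.AVG)
        assert res.swarming_onset == pd.Timestamp("2019-03-12")
        assert res.infestation_onset == pd.Timestamp("2019-03-22")

    def test_cold_year_has_no_onsets(self, params):
        w = generate_series(ClimateSpec(annual_mean=2.0, annual_amplitude=3.0,
                                        diurnal_range=4.0, noise_sd=0.0))
        res = simulate_point(w, 46.37, params)
        assert res.swarming_onset is None
        assert res.infestation_onset is None
        assert res.n_filial == 0 and res.n_sister == 0
        assert all(t.onset_day is None for t in res.broods)

    def test_incomplete_window_rejected(self, params):
        w = generate_series(ClimateSpec(noise_sd=0.0))
        dates = w.dates[: 200]
        from ipsphen import DailyWeatherSeries

        short = DailyWeatherSeries(dates, w.i_min[:200], w.i_mean[:200], w.i_max[:200])
        with pytest.raises(ValueError, match="missing dates"):
            simulate_point(short, 46.37, params)

    def test_deterministic(self, constant_weather, params):
        a = simulate_point(constant_weather, 46.37, params, Scenario.MAX)
        b = simulate_point(constant_weather, 46.37, params, Scenario.MAX)
        assert a.swarming_onset == b.swarming_onset
        for ta, tb in zip(a.broods, b.broods):
            pd.testing.assert_series_equal(ta.tsum, tb.tsum)

    def test_tsum_nondecreasing_and_zero_before_onset(self, params):
        w = generate_series(ClimateSpec(seed=7))
        res = simulate_point(w, 46.37, params)
        for t in res.broods:
            diffs = t.tsum.diff().dropna()
            assert (diffs >= -1e-12).all()
            if t.onset_day is not None:
                assert (t.tsum[t.tsum.index < t.onset_day] == 0).all()

    def test_onset_ordering(self, params):
        for seed in range(5):
            w = generate_series(ClimateSpec(seed=seed, annual_mean=12.0))
            res = simulate_point(w, 46.37, params, Scenario.MAX)
            if res.swarming_onset and res.infestation_onset:
                assert res.swarming_onset <= res.infestation_onset
            order = ["F1", "S1", "F2", "S2", "F3"]
            onsets = [res.brood(b).onset_day for b in order]
            present = [o for o in onsets if o is not None]
            assert present == sorted(present)

    def test_scenario_dominance_below_optimum(self, constant_weather, params):
        res = simulate_scenarios(constant_weather, 46.37, params)
        f1 = {s: r.brood("F1").tsum for s, r in res.items()}
        assert (f1[Scenario.MIN] <= f1[Scenario.AVG] + 1e-12).all()
        assert (f1[Scenario.AVG] <= f1[Scenario.MAX] + 1e-12).all()

    def test_matches_naive_oracle(self, params):
        for seed in (1, 2, 3):
            w = generate_series(ClimateSpec(seed=seed, annual_mean=11.0))
            for scenario in (Scenario.AVG, Scenario.MAX):
                res = simulate_point(w, 46.37, params, scenario)
                swarm, infest, onsets, finals = naive_simulate(w, 46.37, params, scenario)
                assert res.swarming_onset == swarm
                assert res.infestation_onset == infest
                for t in res.broods:
                    assert t.onset_day == onsets.get(t.brood_id), t.brood_id
                    if t.onset_day is not None:
                        assert t.final_tsum == pytest.approx(finals[t.brood_id], abs=1e-9)

    def test_summary_and_daily_frames(self, constant_weather, params):
        res = simulate_point(constant_weather, 46.37, params)
        summary = res.to_summary_frame()
        assert list(summary.columns) == ["scenario", "brood_id", "onset", "final_tsum",
                                         "survives"]
        assert len(summary) == 6
        daily = res.to_daily_frame()
        assert set(daily.columns) == {"date", "scenario", "brood_id", "tsum", "stage"}
        assert len(daily) == 6 * len(res.dates)


class TestModelParameters:
    def test_invariant_checks(self):
        with pytest.raises(ValueError):
            ModelParameters(swarm_dd=200.0)  # swarm above infestation
        with pytest.raises(ValueError):
            ModelParameters(flight_t=5.0)  # below the development threshold
        with pytest.raises(ValueError):
            ModelParameters(hibernation_min=1.5)
        with pytest.raises(ValueError):
            ModelParameters(stage_bounds=(0.5, 0.1, 0.6, 1.0))

    def test_window_respects_leap_years(self):
        p = ModelParameters()
        start, end = p.window(2020)
        assert (start.month, start.day) == (3, 7)
        assert (end - start).days == 238  # window starts after February: leap-independent
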