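import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dailyfit.engine import (
    DEFAULT_PHASE_DURATIONS,
    DEFAULT_WEIGHT_RANGES,
    Phase,
    PhaseSchedule,
    ScheduleError,
    blend_fractions,
    simulate_con,
    simulate_dfm,
    weekly_aggregate,
)
from conftest import make_diet, make_flat_curve, random_increasing_curve


def toy_schedule(durations, diets, next_diets=None):
    next_diets = next_diets or diets[1:] + [diets[-1]]
    phases = tuple(
        Phase(
            index=i + 1,
            duration_days=d,
            weight_range=(0.0, math.inf),
            diet_current=diets[i],
            diet_next=next_diets[i],
        )
        for i, d in enumerate(durations)
    )
    return PhaseSchedule(phases=phases)


class TestBlendFractions:
    def test_phase_start_is_pure_current_feed(self):
        for duration in (1, 7, 24, 120):
            b = blend_fractions(1, duration)
            assert (b.afi1_pct, b.afi2_pct) == (100.0, 0.0)

    def test_midpoint_of_24_day_phase_is_half_and_half(self):
        b = blend_fractions(13, 24)
        assert b.afi1_pct == pytest.approx(50.0, abs=1e-12)
        assert b.afi2_pct == pytest.approx(50.0, abs=1e-12)

    def test_last_day_of_24_day_phase(self):
        b = blend_fractions(24, 24)
        assert b.afi1_pct == pytest.approx(100.0 / 24, abs=1e-12)
        assert b.afi2_pct == pytest.approx(100.0 * 23 / 24, abs=1e-12)

    def test_conservation_over_the_default_schedule(self):
        # every one of the 120 days: shares sum to exactly 100
        for duration in DEFAULT_PHASE_DURATIONS:
            for d in range(1, duration + 1):
                b = blend_fractions(d, duration)
                assert b.afi1_pct + b.afi2_pct == 100.0
                assert 0 <= b.pd_pct < 100

    @given(duration=st.integers(1, 365), data=st.data())
    @settings(derandomize=True, max_examples=200)
    def test_conservation_for_arbitrary_durations(self, duration, data):
        d = data.draw(st.integers(1, duration))
        b = blend_fractions(d, duration)
        assert b.afi1_pct + b.afi2_pct == 100.0
        assert b.afi2_pct == pytest.approx(b.pd_pct, abs=1e-12)

    def test_day_outside_phase_rejected(self):
        with pytest.raises(ScheduleError):
            blend_fractions(0, 10)
        with pytest.raises(ScheduleError):
            blend_fractions(11, 10)


class TestScheduleStructure:
    def test_default_durations_sum_to_120(self):
        assert sum(DEFAULT_PHASE_DURATIONS) == 120

    def test_standard_schedule_needs_six_diets(self):
        diets = [make_diet(f"p{i}", 1.0, cp=100.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        assert sched.horizon == 120
        assert [p.weight_range for p in sched.phases] == list(DEFAULT_WEIGHT_RANGES)
        with pytest.raises(ScheduleError):
            PhaseSchedule.standard(diets[:5])

    def test_phase_of_day_boundaries(self):
        diets = [make_diet(f"p{i}", 1.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        assert sched.phase_of_day(1)[0].index == 1
        assert sched.phase_of_day(24) == (sched.phases[0], 24)
        assert sched.phase_of_day(25) == (sched.phases[1], 1)
        assert sched.phase_of_day(120)[0].index == 5
        assert sched.phase_start_days() == [1, 25, 54, 83, 99]
        with pytest.raises(ScheduleError):
            sched.phase_of_day(121)


class TestConventional:
    def test_flat_single_phase_closed_form(self):
        diet = make_diet("p1", 0.5, cp=100.0)
        sched = toy_schedule([10], [diet], next_diets=[diet])
        curve = make_flat_curve(10, adfi=2.0)
        res = simulate_con(curve, sched)
        assert res.total_cost == pytest.approx(10.0, abs=1e-12)
        assert res.totals["cp"] == pytest.approx(2.0 * 100.0 * 10, abs=1e-9)

    def test_five_default_phases_unit_prices(self):
        diets = [make_diet(f"p{i}", 1.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        res = simulate_con(make_flat_curve(120, adfi=1.0), sched)
        assert res.total_cost == pytest.approx(120.0, abs=1e-9)

    def test_zero_price_decouples_cost_from_intake(self):
        diets = [make_diet(f"p{i}", 0.0, cp=150.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        res = simulate_con(make_flat_curve(120, adfi=2.0), sched)
        assert res.total_cost == 0.0
        assert res.totals["cp"] > 0

    def test_daily_loop_equals_phase_closed_form_on_random_instances(self):
        # CON cost == sum over phases of price * (phase feed mass)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_phases = rng.integers(1, 6)
            durations = rng.integers(2, 15, size=n_phases).tolist()
            prices = rng.uniform(0.2, 3.0, size=n_phases + 1)
            diets = [make_diet(f"p{i}", float(p), cp=100.0) for i, p in enumerate(prices)]
            sched = toy_schedule(durations, diets[:-1], next_diets=diets[1:])
            curve = random_increasing_curve(rng, sum(durations))
            res = simulate_con(curve, sched)
            closed = 0.0
            start = 0
            for phase, dur in zip(sched.phases, durations):
                dfi_sum = sum(d.adfi for d in curve.days[start:start + dur])
                closed += phase.diet_current.price * dfi_sum
                start += dur
            assert res.total_cost == pytest.approx(closed, abs=1e-9)

    def test_horizon_mismatch_rejected(self):
        diets = [make_diet(f"p{i}", 1.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        with pytest.raises(ScheduleError, match="horizon"):
            simulate_con(make_flat_curve(100), sched)


class TestDailyFit:
    def test_four_day_two_phase_hand_enumeration(self):
        # phases of 2 days; feed prices 1.0 / 0.5, anticipated feed 0.25;
        # flat intake 1 kg/day.  Day-by-day blends:
        #   d1: 100% @1.0          -> 1.0
        #   d2: 50% @1.0 + 50%@0.5 -> 0.75
        #   d3: 100% @0.5          -> 0.5
        #   d4: 50% @0.5 + 50%@.25 -> 0.375
        f1 = make_diet("f1", 1.0, cp=200.0)
        f2 = make_diet("f2", 0.5, cp=100.0)
        f3 = make_diet("f3", 0.25, cp=50.0)
        sched = toy_schedule([2, 2], [f1, f2], next_diets=[f2, f3])
        curve = make_flat_curve(4, adfi=1.0)
        res = simulate_dfm(curve, sched)
        assert [r.ctc for r in res.records] == pytest.approx([1.0, 0.75, 0.5, 0.375], abs=1e-12)
        assert res.total_cost == pytest.approx(2.625, abs=1e-12)
        assert res.totals["cp"] == pytest.approx(200 + 150 + 100 + 75, abs=1e-9)

    def test_identical_diets_collapse_to_con(self, mean_growth):
        diet = make_diet("same", 0.9, cp=150.0, sid_lys=9.0)
        diets = [diet] * 6
        sched = PhaseSchedule.standard(diets)
        con = simulate_con(mean_growth, sched)
        dfm = simulate_dfm(mean_growth, sched)
        assert con.total_cost == dfm.total_cost
        assert con.totals == dfm.totals

    def test_phase_start_days_identical_to_con(self, mean_growth):
        diets = [
            make_diet(f"p{i}", 1.5 - 0.1 * i, cp=180.0 - 10 * i, sid_lys=12.0 - i)
            for i in range(1, 7)
        ]
        sched = PhaseSchedule.standard(diets)
        con = simulate_con(mean_growth, sched)
        dfm = simulate_dfm(mean_growth, sched)
        for start in sched.phase_start_days():
            assert con.records[start - 1] == dfm.records[start - 1]

    def test_total_feed_mass_equals_con(self, mean_growth):
        diets = [make_diet(f"p{i}", 1.5 - 0.1 * i, cp=180.0 - 10 * i) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        con = simulate_con(mean_growth, sched)
        dfm = simulate_dfm(mean_growth, sched)
        assert sum(r.dfi for r in con.records) == sum(r.dfi for r in dfm.records)

    def test_monotone_diet_ladders_reduce_every_nutrient_every_day(self, mean_growth):
        # whenever each next feed is nutrient-wise <= the current feed, the
        # daily-fit blend can never ingest more of any nutrient on any day
        rng = np.random.default_rng(7)
        for _ in range(10):
            levels = np.sort(rng.uniform(50, 250, size=6))[::-1]
            lys = np.sort(rng.uniform(4, 14, size=6))[::-1]
            prices = np.sort(rng.uniform(0.8, 1.6, size=6))[::-1]
            diets = [
                make_diet(f"p{i}", float(prices[i]), cp=float(levels[i]), sid_lys=float(lys[i]))
                for i in range(6)
            ]
            sched = PhaseSchedule.standard(diets)
            con = simulate_con(mean_growth, sched)
            dfm = simulate_dfm(mean_growth, sched)
            for k in ("cp", "sid_lys"):
                c = np.cumsum([r.intake[k] for r in con.records])
                d = np.cumsum([r.intake[k] for r in dfm.records])
                assert np.all(d <= c + 1e-9)
            cc = np.cumsum([r.cost for r in con.records])
            dc = np.cumsum([r.cost for r in dfm.records])
            assert np.all(dc <= cc + 1e-9)

    def test_totals_are_sums_of_records(self, mean_growth):
        diets = [make_diet(f"p{i}", 1.0, cp=100.0) for i in range(1, 7)]
        sched = PhaseSchedule.standard(diets)
        res = simulate_dfm(mean_growth, sched)
        assert res.total_cost == sum(r.cost for r in res.records)
        assert res.totals["cp"] == sum(r.intake["cp"] for r in res.records)

    def test_missing_next_diet_rejected(self):
        diet = make_diet("p1", 1.0)
        sched = PhaseSchedule(
            phases=(Phase(1, 4, (0.0, math.inf), diet, None),)
        )
        with pytest.raises(ScheduleError, match="next diet"):
            simulate_dfm(make_flat_curve(4), sched)


class TestWeeklyAggregate:
    def _result(self, horizon):
        diet = make_diet("p1", 1.0, cp=100.0)
        sched = toy_schedule([horizon], [diet], next_diets=[diet])
        return simulate_con(make_flat_curve(horizon, adfi=1.0), sched)

    def test_14_days_make_two_full_weeks(self):
        wk = weekly_aggregate(self._result(14), "cp")
        assert list(wk["week"]) == [1, 2]
        assert not wk["partial"].any()

    def test_16_days_flag_the_trailing_partial_week(self):
        wk = weekly_aggregate(self._result(16), "cp")
        assert list(wk["days"]) == [7, 7, 2]
        assert list(wk["partial"]) == [False, False, True]

    def test_week_totals_conserve_the_run_total(self):
        res = self._result(120)
        wk = weekly_aggregate(res, "cp")
        assert wk["total"].sum() == pytest.approx(res.totals["cp"], abs=1e-9)
        wc = weekly_aggregate(res, "cost")
        assert wc["total"].sum() == pytest.approx(res.total_cost, abs=1e-9)
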