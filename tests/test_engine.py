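"""Cohort engine: rate conversions, phase layout, accrual, conservation, monotonicity."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natcea import (
    Phase,
    PhaseSchedule,
    Strategy,
    drug_cost_schedule,
    monthly_discount_factor,
    monthly_progression_probability,
    monthly_relapse_probability,
    phase_of_cycle,
    run_cohort,
    trace_frame,
)
from natcea.engine import on_treatment_months
from natcea.parameters import Interval, RelapseRateSet
from natcea.synthetic import known_answer_fixture

from conftest import brute_force_totals


class TestRateConversions:
    @pytest.mark.parametrize(
        "arr,expected",
        [(0.0, 0.0), (0.29, 0.0238766), (0.55, 0.0447985)],
    )
    def test_monthly_relapse_probability(self, arr, expected):
        assert monthly_relapse_probability(arr) == pytest.approx(expected, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            monthly_relapse_probability(-0.1)

    @pytest.mark.parametrize(
        "rate,cycle,expected",
        [(0.035, 0, 1.0), (0.035, 12, 1 / 1.035), (0.035, 32, 1.035 ** (-32 / 12))],
    )
    def test_monthly_discount_factor(self, rate, cycle, expected):
        assert monthly_discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "fraction,months,expected",
        [(0.0, 33, 0.0), (0.21, 33, 0.0071168), (0.12, 33, 0.0038659)],
    )
    def test_monthly_progression_probability(self, fraction, months, expected):
        assert monthly_progression_probability(fraction, months) == pytest.approx(
            expected, abs=1e-6
        )

    def test_certain_progression_rejected(self):
        with pytest.raises(ValueError):
            monthly_progression_probability(1.0, 33)

    @settings(max_examples=100, derandomize=True)
    @given(f=st.floats(0.0, 0.99), months=st.integers(1, 60))
    def test_progression_hazard_recovers_horizon_fraction(self, f, months):
        p = monthly_progression_probability(f, months)
        assert 1 - (1 - p) ** months == pytest.approx(f, abs=1e-9)


class TestPhaseLayout:
    @pytest.mark.parametrize(
        "cycle,phase",
        [
            (0, Phase.PRE_CONCEPTION),
            (11, Phase.PRE_CONCEPTION),
            (12, Phase.PREGNANCY),
            (20, Phase.PREGNANCY),
            (21, Phase.POST_PREGNANCY),
            (32, Phase.POST_PREGNANCY),
        ],
    )
    def test_default_schedule_boundaries(self, cycle, phase):
        assert phase_of_cycle(cycle, PhaseSchedule()) is phase

    def test_general_schedule(self):
        sched = PhaseSchedule(6, 9, 3)
        assert phase_of_cycle(5, sched) is Phase.PRE_CONCEPTION
        assert phase_of_cycle(6, sched) is Phase.PREGNANCY
        assert phase_of_cycle(15, sched) is Phase.POST_PREGNANCY
        with pytest.raises(ValueError):
            phase_of_cycle(18, sched)

    def test_on_treatment_month_counts_back_cycle_totals(self):
        # 24 / 27 / 33 treated months at one 4-weekly cycle per 4 weeks
        # correspond to the tabulated totals 6 / 6.75 / 8.25
        sched = PhaseSchedule()
        counts = {s: len(on_treatment_months(s, sched)) for s in Strategy}
        assert counts[Strategy.STOP_AT_CONCEPTION] == 24
        assert counts[Strategy.STOP_AFTER_FIRST_TRIMESTER] == 27
        assert counts[Strategy.CONTINUE_THROUGH_PREGNANCY] == 33
        for s, months in ((s, on_treatment_months(s, sched)) for s in Strategy):
            assert counts[s] / 4 == pytest.approx(
                {
                    Strategy.STOP_AT_CONCEPTION: 6,
                    Strategy.STOP_AFTER_FIRST_TRIMESTER: 6.75,
                    Strategy.CONTINUE_THROUGH_PREGNANCY: 8.25,
                }[s]
            )


class TestDrugCostSchedule:
    def test_originator_stop_at_conception_total(self, base_params):
        stream = drug_cost_schedule(
            Strategy.STOP_AT_CONCEPTION, base_params.drug, base_params.schedule
        )
        assert stream.sum() == pytest.approx(6 * (1130 + 223))

    def test_biosimilar_continue_total(self, base_params):
        drug = dataclasses.replace(
            base_params.drug, price_variant="biosimilar", acquisition_cost_per_cycle=666.0
        )
        stream = drug_cost_schedule(
            Strategy.CONTINUE_THROUGH_PREGNANCY, drug, base_params.schedule
        )
        assert stream.sum() == pytest.approx(8.25 * (666 + 223))
        assert (stream > 0).sum() == 33  # uniform across every month

    def test_zero_cycles_gives_zero_stream(self, base_params):
        drug = dataclasses.replace(
            base_params.drug, total_drug_cycles={s: 0.0 for s in Strategy}
        )
        stream = drug_cost_schedule(Strategy.STOP_AT_CONCEPTION, drug, base_params.schedule)
        assert (stream == 0).all()

    def test_stream_is_zero_off_treatment(self, base_params):
        stream = drug_cost_schedule(
            Strategy.STOP_AT_CONCEPTION, base_params.drug, base_params.schedule
        )
        assert (stream[12:21] == 0).all()  # no drug during pregnancy
        assert (stream[:12] > 0).all() and (stream[21:] > 0).all()


class TestRunCohort:
    def test_null_model_zero_totals(self):
        ka = known_answer_fixture("null_model")
        result = run_cohort(ka.strategy, ka.parameters)
        assert result.total_cost == 0
        assert result.total_qaly == 0

    def test_closed_form_single_band_accrual(self):
        # one band at utility 0.88, nothing else: 33 x 0.88 / 12 = 2.42
        ka = known_answer_fixture("flat_utility")
        params = ka.parameters.replace(
            edss=dataclasses.replace(ka.parameters.edss, band_utility=(0.88, 0.0, 0.0))
        )
        result = run_cohort(Strategy.STOP_AT_CONCEPTION, params)
        assert result.total_qaly == pytest.approx(33 * 0.88 / 12, rel=1e-12)

    def test_breakdown_sums_to_total(self, base_results):
        for result in base_results.values():
            cost_parts = sum(v for k, v in result.breakdown.items() if k.endswith("cost"))
            assert cost_parts == pytest.approx(result.total_cost, rel=1e-9)
            qaly = result.breakdown["edss_qaly"] - result.breakdown["relapse_qaly_loss"]
            assert qaly == pytest.approx(result.total_qaly, rel=1e-9)

    def test_mass_conservation_every_cycle(self, base_params):
        for strategy in Strategy:
            result = run_cohort(strategy, base_params, keep_trace=True)
            initial = sum(base_params.edss.occupancy_vector())
            for state in result.trace:
                assert sum(state.band_occupancy) == pytest.approx(initial, abs=1e-12)

    def test_accumulators_nondecreasing(self, base_params):
        result = run_cohort(Strategy.STOP_AT_CONCEPTION, base_params, keep_trace=True)
        frame = trace_frame(result)
        assert frame["cum_discounted_cost"].is_monotonic_increasing
        assert frame["cum_discounted_qaly"].is_monotonic_increasing

    def test_qaly_ordering_across_strategies(self, base_results):
        q = {s: r.total_qaly for s, r in base_results.items()}
        assert (
            q[Strategy.CONTINUE_THROUGH_PREGNANCY]
            > q[Strategy.STOP_AFTER_FIRST_TRIMESTER]
            > q[Strategy.STOP_AT_CONCEPTION]
        )

    def test_discounting_bound(self, base_params):
        undiscounted = base_params.replace(
            settings=dataclasses.replace(base_params.settings, annual_discount_rate=0.0)
        )
        for strategy in Strategy:
            disc = run_cohort(strategy, base_params)
            flat = run_cohort(strategy, undiscounted)
            assert disc.total_cost < flat.total_cost
            assert disc.total_qaly < flat.total_qaly

    def test_matches_brute_force_oracle_base_case(self, base_params):
        zero_disc = base_params.replace(
            settings=dataclasses.replace(base_params.settings, annual_discount_rate=0.0)
        )
        for params in (base_params, zero_disc):
            for strategy in Strategy:
                result = run_cohort(strategy, params)
                cost, qaly = brute_force_totals(strategy, params)
                assert result.total_cost == pytest.approx(cost, rel=1e-9)
                assert result.total_qaly == pytest.approx(qaly, rel=1e-9)

    def test_invalid_strategy_rejected(self, base_params):
        with pytest.raises(ValueError, match="strategy"):
            run_cohort("continue", base_params)


def _with_arr(params, strategy, phase, value):
    rates = {
        s: {p: params.relapse_rates.rates[s][p] for p in Phase} for s in Strategy
    }
    rates[strategy][phase] = Interval(value, value)
    return params.replace(relapse_rates=RelapseRateSet(rates=rates))


class TestMonotonicity:
    @settings(max_examples=100, derandomize=True)
    @given(
        arr=st.floats(0.0, 2.0),
        phase=st.sampled_from(list(Phase)),
    )
    def test_cost_rises_and_qaly_falls_with_arr(self, base_params, arr, phase):
        strategy = Strategy.STOP_AT_CONCEPTION
        lo = _with_arr(base_params, strategy, phase, arr)
        hi = _with_arr(base_params, strategy, phase, arr + 0.3)
        r_lo, r_hi = run_cohort(strategy, lo), run_cohort(strategy, hi)
        assert r_hi.total_cost >= r_lo.total_cost
        assert r_hi.total_qaly <= r_lo.total_qaly

    @settings(max_examples=100, derandomize=True)
    @given(bump=st.floats(0.001, 0.12), band=st.integers(0, 2))
    def test_qaly_rises_with_utility(self, base_params, bump, band):
        utils = list(base_params.edss.band_utility)
        utils[band] = min(1.0, utils[band] + bump)
        bumped = base_params.replace(
            edss=dataclasses.replace(base_params.edss, band_utility=tuple(utils))
        )
        base = run_cohort(Strategy.CONTINUE_THROUGH_PREGNANCY, base_params)
        more = run_cohort(Strategy.CONTINUE_THROUGH_PREGNANCY, bumped)
        assert more.total_qaly >= base.total_qaly
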