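"""Monthly-cycle Markov cohort engine.

The cohort is tracked as expected occupancy over three EDSS bands across a
33-month horizon (12 months pre-conception, 9 months of pregnancy, 12
months post-pregnancy).  Each cycle the engine

1. resolves the phase and the strategy's point-value annualised relapse
   rate,
2. converts it to a constant-hazard monthly relapse probability and takes
   the occupancy-weighted expectation of relapse events,
3. moves progression mass one EDSS band upward (0-1 -> 2-3 -> 4+, with 4+
   absorbing) at the constant monthly hazard whose 33-month cumulative
   equals the strategy's tabulated progression proportion,
4. accrues discounted cost (relapse events, band-weighted annual EDSS
   costs, the drug cost share of the cycle), and
5. accrues discounted QALYs (band-weighted utilities minus the relapse
   disutility, floored at zero per cycle).

Everything is an expectation: the model is deterministic given parameters
(cohort semantics, no sampled trajectories, no mortality, no improvement
transitions, no washout period).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import (
    BAND_LABELS,
    DrugEconomics,
    EconomicSettings,
    ModelParameters,
    Phase,
    PhaseSchedule,
    Strategy,
)

__all__ = [
    "CohortState",
    "StrategyResult",
    "monthly_relapse_probability",
    "monthly_discount_factor",
    "monthly_progression_probability",
    "phase_of_cycle",
    "on_treatment_months",
    "drug_cost_schedule",
    "run_cohort",
    "run_all_strategies",
    "trace_frame",
    "write_trace_csv",
]


def monthly_relapse_probability(arr: float) -> float:
    """Constant-hazard monthly event probability 1 - exp(-arr/12) for an annualised rate."""
    if arr < 0:
        raise ValueError(f"annualised relapse rate must be >= 0, got {arr}")
    return 1.0 - math.exp(-arr / 12.0)


def monthly_discount_factor(annual_rate: float, cycle_index: int) -> float:
    """Discount factor (1 + r)^(-t/12) for month t; cycle 0 is undiscounted."""
    if not 0 <= annual_rate < 1:
        raise ValueError(f"annual discount rate must be in [0, 1), got {annual_rate}")
    if cycle_index < 0:
        raise ValueError(f"cycle index must be >= 0, got {cycle_index}")
    return (1.0 + annual_rate) ** (-cycle_index / 12.0)


def monthly_progression_probability(horizon_fraction: float, horizon_months: int) -> float:
    """Constant monthly probability whose cumulative over H months equals ``horizon_fraction``."""
    if not 0 <= horizon_fraction < 1:
        raise ValueError(
            f"horizon progression fraction must be in [0, 1), got {horizon_fraction}"
        )
    if horizon_months < 1:
        raise ValueError(f"horizon must be >= 1 month, got {horizon_months}")
    return 1.0 - (1.0 - horizon_fraction) ** (1.0 / horizon_months)


def phase_of_cycle(cycle_index: int, schedule: PhaseSchedule) -> Phase:
    """Phase of a monthly cycle under the given schedule (0-based cycle index)."""
    if not 0 <= cycle_index < schedule.horizon:
        raise ValueError(
            f"cycle {cycle_index} outside the {schedule.horizon}-month horizon"
        )
    if cycle_index < schedule.pre_conception_months:
        return Phase.PRE_CONCEPTION
    if cycle_index < schedule.pre_conception_months + schedule.pregnancy_months:
        return Phase.PREGNANCY
    return Phase.POST_PREGNANCY


def on_treatment_months(strategy: Strategy, schedule: PhaseSchedule) -> tuple[int, ...]:
    """Months in which the strategy is on natalizumab.

    All strategies treat throughout pre-conception and resume
    post-pregnancy; they differ during pregnancy: none of it
    (stop at conception), the first trimester only (stop after first
    trimester), or all of it (continue).  With the default schedule this
    gives 24, 27 and 33 on-treatment months — the month counts that back
    the tabulated 4-weekly cycle totals 6, 6.75 and 8.25.
    """
    pre = schedule.pre_conception_months
    preg = schedule.pregnancy_months
    months = list(range(pre))
    if strategy is Strategy.CONTINUE_THROUGH_PREGNANCY:
        months += list(range(pre, pre + preg))
    elif strategy is Strategy.STOP_AFTER_FIRST_TRIMESTER:
        months += list(range(pre, pre + min(3, preg)))
    months += list(range(pre + preg, schedule.horizon))
    return tuple(months)


def drug_cost_schedule(
    strategy: Strategy, drug: DrugEconomics, schedule: PhaseSchedule
) -> np.ndarray:
    """Per-cycle drug cost stream (GBP), uniform over on-treatment months.

    The tabulated cycle totals are authoritative; their undiscounted sum,
    cycles x (acquisition + administration), is spread evenly across the
    strategy's on-treatment months so discounting is well defined.
    """
    cycles = drug.total_drug_cycles[strategy]
    total = cycles * (drug.acquisition_cost_per_cycle + drug.administration_cost_per_cycle)
    stream = np.zeros(schedule.horizon)
    if total > 0:
        months = on_treatment_months(strategy, schedule)
        stream[list(months)] = total / len(months)
    return stream


@dataclass(frozen=True)
class CohortState:
    """Snapshot of the cohort at the end of one monthly cycle."""

    cycle_index: int
    phase: Phase
    band_occupancy: tuple[float, ...]
    unclassified: float
    expected_relapses: float
    discount_factor: float
    cycle_cost: float
    cycle_qaly: float
    cum_discounted_cost: float
    cum_discounted_qaly: float


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-person totals for one strategy (one base-case table row)."""

    strategy: Strategy
    total_cost: float
    total_qaly: float
    breakdown: dict[str, float]
    settings: EconomicSettings
    trace: tuple[CohortState, ...] = field(default=(), repr=False, compare=False)


def run_cohort(
    strategy: Strategy, params: ModelParameters, keep_trace: bool = False
) -> StrategyResult:
    """Simulate the monthly Markov cohort for one strategy.

    Returns discounted per-person totals with a cost/QALY breakdown
    (drug acquisition, administration, relapse cost, EDSS cost; EDSS
    utility accrual and relapse QALY loss).  ``keep_trace`` attaches the
    per-cycle state sequence for audit and oracle testing.
    """
    if not isinstance(strategy, Strategy):
        raise ValueError(f"unknown strategy {strategy!r}")
    params.validate()

    schedule = params.schedule
    horizon = schedule.horizon
    occupancy = np.array(params.edss.occupancy_vector(), dtype=float)
    unclassified = params.edss.unclassified
    band_costs = np.array(params.edss.band_costs(), dtype=float)
    utilities = np.array(params.edss.band_utility, dtype=float)

    p_prog = monthly_progression_probability(
        params.progression.proportions[strategy], horizon
    )
    drug_stream = drug_cost_schedule(strategy, params.drug, schedule)
    acq = params.drug.acquisition_cost_per_cycle
    admin = params.drug.administration_cost_per_cycle
    acq_share = acq / (acq + admin) if acq + admin > 0 else 0.0
    rate = params.settings.annual_discount_rate
    c_rel = params.relapse_econ.cost_per_relapse
    d_rel = params.relapse_econ.disutility_per_relapse

    totals = {
        "drug_acquisition_cost": 0.0,
        "drug_administration_cost": 0.0,
        "relapse_cost": 0.0,
        "edss_cost": 0.0,
        "edss_qaly": 0.0,
        "relapse_qaly_loss": 0.0,
    }
    cum_cost = cum_qaly = 0.0
    trace: list[CohortState] = []

    for t in range(horizon):
        phase = phase_of_cycle(t, schedule)
        arr = params.relapse_rates.midpoint(strategy, phase)
        expected_relapses = monthly_relapse_probability(arr) * occupancy.sum()

        # one-band-upward progression; the top band absorbs
        moved = occupancy[:-1] * p_prog
        occupancy = occupancy + np.concatenate(([0.0], moved)) - np.concatenate((moved, [0.0]))

        factor = monthly_discount_factor(rate, t)

        relapse_cost = expected_relapses * c_rel
        edss_cost = float(occupancy @ band_costs) / 12.0
        drug_cost = float(drug_stream[t])
        cycle_cost = relapse_cost + edss_cost + drug_cost

        qaly_gain = float(occupancy @ utilities) / 12.0
        qaly_loss = expected_relapses * d_rel
        # per-cycle floor: the relapse decrement never drives accrual negative
        qaly_loss = min(qaly_loss, qaly_gain)
        cycle_qaly = qaly_gain - qaly_loss

        totals["relapse_cost"] += relapse_cost * factor
        totals["edss_cost"] += edss_cost * factor
        totals["drug_acquisition_cost"] += drug_cost * acq_share * factor
        totals["drug_administration_cost"] += drug_cost * (1.0 - acq_share) * factor
        totals["edss_qaly"] += qaly_gain * factor
        totals["relapse_qaly_loss"] += qaly_loss * factor
        cum_cost += cycle_cost * factor
        cum_qaly += cycle_qaly * factor

        if keep_trace:
            trace.append(
                CohortState(
                    cycle_index=t,
                    phase=phase,
                    band_occupancy=tuple(occupancy),
                    unclassified=unclassified,
                    expected_relapses=expected_relapses,
                    discount_factor=factor,
                    cycle_cost=cycle_cost,
                    cycle_qaly=cycle_qaly,
                    cum_discounted_cost=cum_cost,
                    cum_discounted_qaly=cum_qaly,
                )
            )

    return StrategyResult(
        strategy=strategy,
        total_cost=cum_cost,
        total_qaly=cum_qaly,
        breakdown=totals,
        settings=params.settings,
        trace=tuple(trace),
    )


def run_all_strategies(
    params: ModelParameters, keep_trace: bool = False
) -> dict[Strategy, StrategyResult]:
    """Run the cohort engine for all three strategies on one parameter set."""
    return {s: run_cohort(s, params, keep_trace=keep_trace) for s in Strategy}


def trace_frame(result: StrategyResult) -> pd.DataFrame:
    """Per-cycle audit trace as a DataFrame (requires ``keep_trace=True``)."""
    if not result.trace:
        raise ValueError("result has no trace; rerun with keep_trace=True")
    rows = []
    for st in result.trace:
        row = {
            "cycle": st.cycle_index,
            "phase": st.phase.value,
            "expected_relapses": st.expected_relapses,
            "discount_factor": st.discount_factor,
            "cycle_cost": st.cycle_cost,
            "cycle_qaly": st.cycle_qaly,
            "cum_discounted_cost": st.cum_discounted_cost,
            "cum_discounted_qaly": st.cum_discounted_qaly,
            "unclassified": st.unclassified,
        }
        for label, occ in zip(BAND_LABELS, st.band_occupancy):
            row[f"occupancy_{label}"] = occ
        rows.append(row)
    return pd.DataFrame(rows)


def write_trace_csv(result: StrategyResult, path: str | Path) -> None:
    trace_frame(result).to_csv(path, index=False)
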