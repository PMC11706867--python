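"""Shared fixtures and the independent brute-force cohort oracle.

The oracle re-derives per-strategy totals by plain per-cycle arithmetic
(pure Python, no shared code with the engine) so engine totals can be
checked against an independent accumulation.
"""

from __future__ import annotations

import math

import pytest

from natcea import (
    ModelParameters,
    Phase,
    Strategy,
    default_parameters,
    run_all_strategies,
)


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def base_results(base_params):
    return run_all_strategies(base_params)


def brute_force_totals(strategy: Strategy, params: ModelParameters):
    """Independent per-cycle accumulation of discounted cost and QALY totals."""
    sched = params.schedule
    horizon = sched.pre_conception_months + sched.pregnancy_months + sched.post_pregnancy_months

    occ = list(params.edss.occupancy_vector())
    band_costs = []
    for lo, hi in params.edss.band_level_ranges:
        members = params.edss.level_costs[lo : hi + 1]
        band_costs.append(sum(members) / len(members))
    utils = list(params.edss.band_utility)

    f = params.progression.proportions[strategy]
    p_prog = 1.0 - (1.0 - f) ** (1.0 / horizon)

    # on-treatment months: pre-conception, pregnancy share, post-pregnancy resumption
    pre, preg = sched.pre_conception_months, sched.pregnancy_months
    months = set(range(pre)) | set(range(pre + preg, horizon))
    if strategy is Strategy.CONTINUE_THROUGH_PREGNANCY:
        months |= set(range(pre, pre + preg))
    elif strategy is Strategy.STOP_AFTER_FIRST_TRIMESTER:
        months |= set(range(pre, pre + min(3, preg)))
    drug_total = params.drug.total_drug_cycles[strategy] * (
        params.drug.acquisition_cost_per_cycle + params.drug.administration_cost_per_cycle
    )
    drug_per_month = drug_total / len(months) if drug_total > 0 else 0.0

    rate = params.settings.annual_discount_rate
    cost = qaly = 0.0
    for t in range(horizon):
        if t < pre:
            phase = Phase.PRE_CONCEPTION
        elif t < pre + preg:
            phase = Phase.PREGNANCY
        else:
            phase = Phase.POST_PREGNANCY
        iv = params.relapse_rates.rates[strategy][phase]
        arr = (iv.low + iv.high) / 2.0
        relapses = (1.0 - math.exp(-arr / 12.0)) * sum(occ)

        moved = [occ[i] * p_prog for i in range(len(occ) - 1)]
        occ = [
            occ[0] - moved[0],
            occ[1] + moved[0] - moved[1],
            occ[2] + moved[1],
        ]

        disc = (1.0 + rate) ** (-t / 12.0)
        c = relapses * params.relapse_econ.cost_per_relapse
        c += sum(o * bc for o, bc in zip(occ, band_costs)) / 12.0
        if t in months:
            c += drug_per_month
        gain = sum(o * u for o, u in zip(occ, utils)) / 12.0
        loss = min(relapses * params.relapse_econ.disutility_per_relapse, gain)
        cost += c * disc
        qaly += (gain - loss) * disc
    return cost, qaly
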