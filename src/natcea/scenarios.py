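"""Named deterministic analyses: base case, price variants, alternative progression, WTP.

A scenario applies a drug price variant (originator, generic or
biosimilar), a progression-interpolation choice (linear or logarithmic)
and a willingness-to-pay threshold to a base parameter set, runs all
three strategies deterministically, and reports per-strategy totals plus
incrementals versus stopping at conception.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .economics import (
    IncrementalResult,
    compute_incremental,
    incremental_table,
    strategy_table,
)
from .engine import StrategyResult, run_all_strategies
from .parameters import (
    PRICE_VARIANTS,
    REFERENCE_STRATEGY,
    ModelParameters,
    Strategy,
    _deep_merge,
    _params_from_dict,
    _params_to_dict,
    progression_log,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioReport",
    "NAMED_SCENARIOS",
    "apply_scenario",
    "run_scenario",
    "run_all_scenarios",
    "scenario_summary",
]


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    price_variant: str = "originator"
    progression_interpolation: str = "linear"  # "linear" | "logarithmic"
    wtp: float = 20000.0
    overrides: dict | None = None


#: The named analyses run by the `scenarios` command.
NAMED_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec(name="base_case"),
    ScenarioSpec(name="generic_price", price_variant="generic"),
    ScenarioSpec(name="biosimilar_price", price_variant="biosimilar"),
    ScenarioSpec(name="log_progression", progression_interpolation="logarithmic"),
    ScenarioSpec(name="wtp_30000", wtp=30000.0),
)


@dataclass(frozen=True)
class ScenarioReport:
    spec: ScenarioSpec
    parameters: ModelParameters
    results: dict[Strategy, StrategyResult]
    incrementals: dict[Strategy, IncrementalResult]

    def strategy_frame(self) -> pd.DataFrame:
        return strategy_table(self.results)

    def incremental_frame(self) -> pd.DataFrame:
        return incremental_table(self.results, self.spec.wtp)


def apply_scenario(spec: ScenarioSpec, base: ModelParameters) -> ModelParameters:
    """Resolve a scenario into a concrete parameter set."""
    if spec.price_variant not in PRICE_VARIANTS:
        raise ValueError(
            f"unknown price variant {spec.price_variant!r}; "
            f"expected one of {sorted(PRICE_VARIANTS)}"
        )
    params = base.replace(
        drug=replace(
            base.drug,
            price_variant=spec.price_variant,
            acquisition_cost_per_cycle=PRICE_VARIANTS[spec.price_variant],
        )
    )
    if spec.progression_interpolation == "logarithmic":
        # refit through the two observed anchors (the discontinuation
        # strategies) and re-derive only the continuation proportion, the
        # one input the linear base case interpolates rather than observes
        props = dict(params.progression.proportions)
        anchors = (
            (1.0, props[Strategy.STOP_AT_CONCEPTION] * 100.0),
            (2.0, props[Strategy.STOP_AFTER_FIRST_TRIMESTER] * 100.0),
        )
        props[Strategy.CONTINUE_THROUGH_PREGNANCY] = (
            progression_log(anchors[0], anchors[1], 3.0) / 100.0
        )
        params = params.replace(progression=replace(params.progression, proportions=props))
    elif spec.progression_interpolation != "linear":
        raise ValueError(
            f"unknown progression interpolation {spec.progression_interpolation!r}"
        )
    if spec.overrides:
        data = _deep_merge(_params_to_dict(params), spec.overrides)
        params = _params_from_dict(data)
    params.validate()
    return params


def run_scenario(spec: ScenarioSpec, base: ModelParameters) -> ScenarioReport:
    """Run one named analysis end to end."""
    params = apply_scenario(spec, base)
    results = run_all_strategies(params)
    incrementals = {
        s: compute_incremental(results[s], results[REFERENCE_STRATEGY], spec.wtp)
        for s in Strategy
        if s is not REFERENCE_STRATEGY
    }
    return ScenarioReport(
        spec=spec, parameters=params, results=results, incrementals=incrementals
    )


def run_all_scenarios(
    base: ModelParameters, specs: tuple[ScenarioSpec, ...] = NAMED_SCENARIOS
) -> dict[str, ScenarioReport]:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("scenario names must be unique within a run manifest")
    return {spec.name: run_scenario(spec, base) for spec in specs}


def scenario_summary(reports: dict[str, ScenarioReport]) -> pd.DataFrame:
    """One combined frame: scenario x strategy totals and incrementals."""
    rows = []
    for name, report in reports.items():
        for s in Strategy:
            r = report.results[s]
            inc = report.incrementals.get(s)
            rows.append(
                {
                    "scenario": name,
                    "wtp": report.spec.wtp,
                    "strategy": s.value,
                    "total_cost": r.total_cost,
                    "total_qaly": r.total_qaly,
                    "delta_cost": None if inc is None else inc.delta_cost,
                    "delta_qaly": None if inc is None else inc.delta_qaly,
                    "icer": None if inc is None else inc.icer,
                    "nmb": None if inc is None else inc.nmb,
                    "dominance": None if inc is None else inc.dominance.value,
                }
            )
    return pd.DataFrame(rows)
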