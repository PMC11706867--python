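"""Incremental cost-effectiveness statistics.

For a strategy against a reference: incremental cost ΔC, incremental
effect ΔE (QALYs), the incremental cost-effectiveness ratio ICER = ΔC/ΔE,
and the net monetary benefit NMB = λ·ΔE − ΔC at willingness-to-pay λ.
A strategy is cost-effective at λ when NMB > 0 (strict), which for
ΔE > 0 is equivalent to ICER < λ.  Dominance is classified from the
signs of ΔC and ΔE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .engine import StrategyResult
from .parameters import REFERENCE_STRATEGY, Strategy

__all__ = [
    "Dominance",
    "IncrementalResult",
    "compute_incremental",
    "cost_effective",
    "net_monetary_benefit",
    "incremental_table",
    "strategy_table",
    "write_results_csv",
]


class Dominance(str, enum.Enum):
    DOMINANT = "dominant"        # cheaper and at least as effective
    DOMINATED = "dominated"      # costlier and at most as effective
    TRADE_OFF = "trade_off"      # more costly and more effective (or the reverse)
    EQUIVALENT = "equivalent"    # identical costs and effects


@dataclass(frozen=True)
class IncrementalResult:
    """One incremental-table row: a strategy versus the reference strategy."""

    strategy: Strategy
    reference: Strategy
    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb: float
    wtp: float
    dominance: Dominance


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = λ·ΔE − ΔC; positive means cost-effective at threshold λ."""
    return wtp * delta_qaly - delta_cost


def _classify(delta_cost: float, delta_qaly: float) -> Dominance:
    if delta_cost == 0 and delta_qaly == 0:
        return Dominance.EQUIVALENT
    if delta_cost <= 0 and delta_qaly >= 0:
        return Dominance.DOMINANT
    if delta_cost >= 0 and delta_qaly <= 0:
        return Dominance.DOMINATED
    return Dominance.TRADE_OFF


def compute_incremental(
    result: StrategyResult, reference: StrategyResult, wtp: float
) -> IncrementalResult:
    """Incremental economics of ``result`` versus ``reference`` at threshold ``wtp``.

    The ICER is reported as ``None`` (undefined) when ΔE = 0; ranking then
    falls back to NMB.  Both results must come from runs under identical
    economic settings.
    """
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay must be positive, got {wtp}")
    if result.settings != reference.settings:
        raise ValueError(
            "mismatched economic settings between result and reference runs"
        )
    delta_cost = result.total_cost - reference.total_cost
    delta_qaly = result.total_qaly - reference.total_qaly
    icer = None if delta_qaly == 0 else delta_cost / delta_qaly
    return IncrementalResult(
        strategy=result.strategy,
        reference=reference.strategy,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        nmb=net_monetary_benefit(delta_cost, delta_qaly, wtp),
        wtp=wtp,
        dominance=_classify(delta_cost, delta_qaly),
    )


def cost_effective(incremental: IncrementalResult, wtp: float | None = None) -> bool:
    """Decision rule: cost-effective iff NMB at λ is strictly positive.

    Equivalent to ΔC/ΔE < λ when ΔE > 0.  Dominant comparisons are always
    cost-effective, dominated ones never.  ``wtp`` defaults to the λ the
    incremental was computed at.
    """
    if wtp is None:
        wtp = incremental.wtp
    return net_monetary_benefit(incremental.delta_cost, incremental.delta_qaly, wtp) > 0


def strategy_table(results: dict[Strategy, StrategyResult]) -> pd.DataFrame:
    """Per-strategy totals (base-case costs/QALYs table shape)."""
    rows = [
        {
            "strategy": s.value,
            "total_cost": r.total_cost,
            "total_qaly": r.total_qaly,
            **r.breakdown,
        }
        for s, r in results.items()
    ]
    return pd.DataFrame(rows)


def incremental_table(
    results: dict[Strategy, StrategyResult],
    wtp: float,
    reference: Strategy = REFERENCE_STRATEGY,
) -> pd.DataFrame:
    """Incremental-table frame versus the reference strategy.

    The reference row carries nulls in the incremental columns (rendered
    as dashes in the human-readable table).
    """
    ref = results[reference]
    rows = []
    for s, r in results.items():
        if s is reference:
            rows.append(
                {
                    "strategy": s.value,
                    "delta_cost": None,
                    "delta_qaly": None,
                    "icer": None,
                    "nmb": None,
                    "dominance": None,
                }
            )
            continue
        inc = compute_incremental(r, ref, wtp)
        rows.append(
            {
                "strategy": s.value,
                "delta_cost": inc.delta_cost,
                "delta_qaly": inc.delta_qaly,
                "icer": inc.icer,
                "nmb": inc.nmb,
                "dominance": inc.dominance.value,
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(
    results: dict[Strategy, StrategyResult],
    wtp: float,
    directory: str | Path,
    reference: Strategy = REFERENCE_STRATEGY,
) -> tuple[Path, Path]:
    """Write the per-strategy and incremental tables as CSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    strat_path = directory / "strategy_results.csv"
    inc_path = directory / "incrementals.csv"
    strategy_table(results).to_csv(strat_path, index=False)
    incremental_table(results, wtp, reference).to_csv(inc_path, index=False)
    return strat_path, inc_path
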