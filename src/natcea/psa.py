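"""Probabilistic sensitivity analysis.

Each draw perturbs the base-case inputs and re-runs the cohort engine for
all three strategies on the common perturbed set (correlated PSA).  The
±20% adjustment range is read as a 95% interval of the perturbation
distribution, i.e. SD = range × mean / 1.96, moment-matched to a beta
distribution for proportions and rates and a gamma distribution for
costs.  Utilities, drug cycle counts, the schedule and the discount rate
are held fixed.

Uncertainty is summarised as cost-effectiveness-plane points per draw and
as cost-effectiveness acceptability curves (CEAC): for each
willingness-to-pay value, the fraction of draws in which each strategy
has the highest net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import run_cohort
from .parameters import (
    REFERENCE_STRATEGY,
    Interval,
    ModelParameters,
    Phase,
    RelapseRateSet,
    Strategy,
)

__all__ = [
    "PsaSample",
    "CeacCurve",
    "DEFAULT_WTP_GRID",
    "draw_parameters",
    "run_psa",
    "ceac",
    "ce_plane_frame",
    "ceac_frame",
    "acceptability",
    "plot_ceac",
]

#: Default CEAC grid: £0 to £50,000 per QALY in £1,000 steps.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 50001, 1000))

# beta draws are only well defined on (0, 1); rates at or above this
# threshold fall back to the gamma family, which preserves the moments
_BETA_SUPPORT_LIMIT = 0.95


@dataclass(frozen=True)
class PsaSample:
    """One PSA draw: the perturbed inputs and the (cost, QALY) pair per strategy."""

    draw_index: int
    parameters: ModelParameters
    outcomes: dict[Strategy, tuple[float, float]]


@dataclass(frozen=True)
class CeacCurve:
    """Acceptability probabilities per strategy over a willingness-to-pay grid."""

    wtp_grid: tuple[float, ...]
    probability: dict[Strategy, tuple[float, ...]]


def _beta_proportion(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched beta draw on [0, 1]."""
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:  # variance too large for a beta with this mean; degrade to gamma
        return _gamma_cost(rng, mean, sd)
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_cost(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched gamma draw on [0, inf)."""
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, mean / shape))


def _perturb_rate(rng: np.random.Generator, base: float, rel_sd: float) -> float:
    """Beta draw for a proportion/rate; gamma fallback when the support is exceeded."""
    if base <= 0:
        return 0.0
    sd = rel_sd * base
    if base >= _BETA_SUPPORT_LIMIT:
        return _gamma_cost(rng, base, sd)
    return _beta_proportion(rng, base, sd)


def draw_parameters(
    base: ModelParameters, rng_seed: int, draw_index: int
) -> ModelParameters:
    """One perturbed parameter set, deterministic in (rng_seed, draw_index).

    Perturbs every ARR point value, the progression proportions, the
    baseline band occupancy (beta family), and every cost: per-relapse,
    the EDSS level ladder, drug acquisition and administration (gamma
    family).  A zero base value is held at zero; a zero perturbation
    range returns the base set unchanged.
    """
    rel_range = base.settings.psa_range
    if rel_range == 0:
        return base
    rel_sd = rel_range / 1.96
    rng = np.random.default_rng([int(rng_seed), int(draw_index)])

    rates = {
        s: {
            p: Interval(v := _perturb_rate(rng, base.relapse_rates.midpoint(s, p), rel_sd), v)
            for p in Phase
        }
        for s in Strategy
    }
    proportions = {
        s: _perturb_rate(rng, base.progression.proportions[s], rel_sd) for s in Strategy
    }
    occupancy = [
        _perturb_rate(rng, o, rel_sd) for o in base.edss.baseline_occupancy
    ]
    total = sum(occupancy)
    if total > 1.0:  # keep the band vector on the simplex
        occupancy = [o / total for o in occupancy]

    cost_per_relapse = _gamma_cost(
        rng, base.relapse_econ.cost_per_relapse, rel_sd * base.relapse_econ.cost_per_relapse
    )
    level_costs = tuple(
        _gamma_cost(rng, c, rel_sd * c) if c > 0 else 0.0 for c in base.edss.level_costs
    )
    acq = base.drug.acquisition_cost_per_cycle
    admin = base.drug.administration_cost_per_cycle
    acq = _gamma_cost(rng, acq, rel_sd * acq) if acq > 0 else 0.0
    admin = _gamma_cost(rng, admin, rel_sd * admin) if admin > 0 else 0.0

    return base.replace(
        relapse_rates=RelapseRateSet(rates=rates),
        progression=replace(base.progression, proportions=proportions),
        edss=replace(
            base.edss,
            baseline_occupancy=tuple(occupancy),
            level_costs=level_costs,
        ),
        relapse_econ=replace(base.relapse_econ, cost_per_relapse=cost_per_relapse),
        drug=replace(
            base.drug,
            acquisition_cost_per_cycle=acq,
            administration_cost_per_cycle=admin,
        ),
    )


def run_psa(
    base: ModelParameters, n_draws: int | None = None, rng_seed: int = 0
) -> list[PsaSample]:
    """Run the PSA: one perturbed set per draw, all strategies on that set.

    ``n_draws`` defaults to the parameter set's configured draw count.
    Engine failures abort with the offending draw index.
    """
    if n_draws is None:
        n_draws = base.settings.psa_draws
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    samples = []
    for i in range(n_draws):
        perturbed = draw_parameters(base, rng_seed, i)
        try:
            outcomes = {
                s: (r.total_cost, r.total_qaly)
                for s, r in ((s, run_cohort(s, perturbed)) for s in Strategy)
            }
        except Exception as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        samples.append(PsaSample(draw_index=i, parameters=perturbed, outcomes=outcomes))
    return samples


def ceac(samples: Sequence[PsaSample], wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CeacCurve:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    Per grid point and strategy: the fraction of draws in which the
    strategy's net monetary benefit λ·E − C is strictly greatest, with
    ties split equally.
    """
    if len(samples) == 0:
        raise ValueError("empty PSA sample collection")
    grid = [float(w) for w in wtp_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("wtp_grid must be strictly ascending")
    strategies = list(Strategy)
    costs = np.array([[s.outcomes[st][0] for st in strategies] for s in samples])
    qalys = np.array([[s.outcomes[st][1] for st in strategies] for s in samples])
    prob = {st: [] for st in strategies}
    n = len(samples)
    for lam in grid:
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        share = winners / winners.sum(axis=1, keepdims=True)
        for j, st in enumerate(strategies):
            prob[st].append(float(share[:, j].sum() / n))
    return CeacCurve(
        wtp_grid=tuple(grid), probability={st: tuple(v) for st, v in prob.items()}
    )


def acceptability(samples: Sequence[PsaSample], strategy: Strategy, wtp: float) -> float:
    """Probability the strategy has the highest NMB at one threshold."""
    curve = ceac(samples, [wtp])
    return curve.probability[strategy][0]


def ce_plane_frame(
    samples: Sequence[PsaSample], reference: Strategy = REFERENCE_STRATEGY
) -> pd.DataFrame:
    """Cost-effectiveness-plane points: incremental cost/QALY per draw and strategy.

    One row per draw and strategy (reference rows carry zero increments),
    so a run of n draws exports 3n points.
    """
    rows = []
    for s in samples:
        ref_cost, ref_qaly = s.outcomes[reference]
        for st in Strategy:
            c, q = s.outcomes[st]
            rows.append(
                {
                    "draw": s.draw_index,
                    "strategy": st.value,
                    "incremental_cost": c - ref_cost,
                    "incremental_qaly": q - ref_qaly,
                }
            )
    return pd.DataFrame(rows)


def ceac_frame(curve: CeacCurve) -> pd.DataFrame:
    data = {"wtp": list(curve.wtp_grid)}
    for st in Strategy:
        data[st.value] = list(curve.probability[st])
    return pd.DataFrame(data)


def plot_ceac(curve: CeacCurve, path: str | Path) -> None:
    """Render the acceptability curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for st in Strategy:
        ax.plot(curve.wtp_grid, curve.probability[st], label=st.value.replace("_", " "))
    ax.set_xlabel("Willingness to pay (GBP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
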