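"""Synthetic parameter sets and closed-form known-answer fixtures.

No patient-level data backs this model — its inputs are cohort-level
rates, proportions, utilities and unit costs.  This module generates
whole parameter sets with that statistical shape (dispersed around the
packaged base case, with every structural invariant enforced) so the
engine, economics and PSA layers can be exercised on inputs other than
the single published set, and provides degenerate parameter sets whose
cohort results have closed forms for oracle testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    EdssStructure,
    Interval,
    ModelParameters,
    Phase,
    RelapseEconomics,
    RelapseRateSet,
    Strategy,
    default_parameters,
)

__all__ = [
    "SyntheticSpec",
    "KnownAnswer",
    "generate_parameter_sets",
    "known_answer_fixture",
    "FIXTURE_NAMES",
]

#: Plausibility envelope for synthetic annualised relapse rates
#: (events/person-year), spanning the magnitudes of the base-case table.
ARR_ENVELOPE = (0.1, 1.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Controls for the generator: seed, count, dispersion, and which blocks vary."""

    rng_seed: int = 0
    n_sets: int = 1
    jitter: float = 0.0
    structure_flags: frozenset[str] = frozenset({"rates", "costs", "utilities", "occupancy"})

    def validate(self) -> None:
        if self.jitter < 0:
            raise ValueError(f"jitter must be >= 0, got {self.jitter}")
        if self.n_sets < 1:
            raise ValueError(f"n_sets must be >= 1, got {self.n_sets}")
        unknown = self.structure_flags - {"rates", "costs", "utilities", "occupancy"}
        if unknown:
            raise ValueError(f"unknown structure flags: {sorted(unknown)}")


def _jitter_factor(rng: np.random.Generator, jitter: float) -> float:
    # multiplicative, symmetric on the log scale, bounded away from 0
    return float(np.exp(rng.normal(0.0, jitter)))


def _synthetic_rates(rng: np.random.Generator, base: RelapseRateSet, jitter: float) -> RelapseRateSet:
    lo_env, hi_env = ARR_ENVELOPE
    rates = {}
    for s in Strategy:
        per_phase = {}
        for p in Phase:
            iv = base.rates[s][p]
            mid = float(np.clip(iv.midpoint * _jitter_factor(rng, jitter), lo_env * 0.5, hi_env))
            half = 0.5 * (iv.high - iv.low) * _jitter_factor(rng, jitter)
            low = max(0.0, mid - half)
            per_phase[p] = Interval(low, low + 2 * half)
        rates[s] = per_phase
    return RelapseRateSet(rates=rates)


def _synthetic_edss(rng: np.random.Generator, base: EdssStructure, jitter: float,
                    flags: frozenset[str]) -> EdssStructure:
    occupancy = np.array(base.baseline_occupancy, dtype=float)
    if "occupancy" in flags:
        occupancy = occupancy * np.array(
            [_jitter_factor(rng, jitter) for _ in occupancy]
        )
        occupancy = occupancy / occupancy.sum() * sum(base.baseline_occupancy)
    utilities = np.array(base.band_utility, dtype=float)
    if "utilities" in flags:
        utilities = np.clip(
            utilities * np.array([_jitter_factor(rng, jitter) for _ in utilities]),
            0.0, 1.0,
        )
        utilities = np.sort(utilities)[::-1]  # utility decreases with disability
    level_costs = np.array(base.level_costs, dtype=float)
    if "costs" in flags:
        for _ in range(100):
            cand = level_costs * np.array(
                [_jitter_factor(rng, jitter) for _ in level_costs]
            )
            means = [
                cand[lo : hi + 1].mean() for lo, hi in base.band_level_ranges
            ]
            if all(a <= b for a, b in zip(means, means[1:])):
                level_costs = cand
                break
        else:  # keep the base ladder rather than emit a non-monotone one
            pass
    return replace(
        base,
        baseline_occupancy=tuple(float(o) for o in occupancy),
        band_utility=tuple(float(u) for u in utilities),
        level_costs=tuple(float(c) for c in level_costs),
    )


def generate_parameter_sets(spec: SyntheticSpec) -> list[ModelParameters]:
    """Emit ``n_sets`` valid parameter sets dispersed around the base case.

    With ``jitter == 0`` every emitted set equals the packaged defaults.
    Every set satisfies the full validation contract and round-trips
    through the configuration reader/writer; draws are reproducible from
    the seed.
    """
    spec.validate()
    base = default_parameters()
    rng = np.random.default_rng(spec.rng_seed)
    out = []
    for _ in range(spec.n_sets):
        params = base
        if spec.jitter > 0:
            if "rates" in spec.structure_flags:
                params = params.replace(
                    relapse_rates=_synthetic_rates(rng, base.relapse_rates, spec.jitter)
                )
                props = {
                    s: float(np.clip(
                        base.progression.proportions[s] * _jitter_factor(rng, spec.jitter),
                        0.0, 0.95,
                    ))
                    for s in Strategy
                }
                params = params.replace(
                    progression=replace(base.progression, proportions=props)
                )
            params = params.replace(
                edss=_synthetic_edss(rng, base.edss, spec.jitter, spec.structure_flags)
            )
            if "costs" in spec.structure_flags:
                params = params.replace(
                    relapse_econ=RelapseEconomics(
                        disutility_per_relapse=base.relapse_econ.disutility_per_relapse,
                        cost_per_relapse=base.relapse_econ.cost_per_relapse
                        * _jitter_factor(rng, spec.jitter),
                    ),
                    drug=replace(
                        base.drug,
                        acquisition_cost_per_cycle=base.drug.acquisition_cost_per_cycle
                        * _jitter_factor(rng, spec.jitter),
                        administration_cost_per_cycle=base.drug.administration_cost_per_cycle
                        * _jitter_factor(rng, spec.jitter),
                    ),
                )
        params.validate()
        out.append(params)
    return out


@dataclass(frozen=True)
class KnownAnswer:
    """A degenerate parameter set with analytically known cohort totals."""

    name: str
    parameters: ModelParameters
    strategy: Strategy
    expected_cost: float
    expected_qaly: float


def _degenerate_base() -> ModelParameters:
    """All-zero rates, costs, utilities, progression and discounting."""
    base = default_parameters()
    zero_iv = Interval(0.0, 0.0)
    return base.replace(
        relapse_rates=RelapseRateSet(
            rates={s: {p: zero_iv for p in Phase} for s in Strategy}
        ),
        progression=replace(
            base.progression, proportions={s: 0.0 for s in Strategy}
        ),
        edss=replace(
            base.edss,
            band_utility=(0.0, 0.0, 0.0),
            level_costs=(0.0,) * 10,
        ),
        relapse_econ=RelapseEconomics(disutility_per_relapse=0.0, cost_per_relapse=0.0),
        drug=replace(
            base.drug,
            acquisition_cost_per_cycle=0.0,
            administration_cost_per_cycle=0.0,
        ),
        settings=replace(base.settings, annual_discount_rate=0.0),
    )


def _fixture_null() -> KnownAnswer:
    return KnownAnswer(
        name="null_model",
        parameters=_degenerate_base(),
        strategy=Strategy.STOP_AT_CONCEPTION,
        expected_cost=0.0,
        expected_qaly=0.0,
    )


def _fixture_flat_utility() -> KnownAnswer:
    # whole cohort in one band at utility 0.75, nothing else active:
    # QALY = 33 months x 0.75 / 12 = 2.0625
    params = _degenerate_base()
    params = params.replace(
        edss=replace(
            params.edss,
            baseline_occupancy=(1.0, 0.0, 0.0),
            band_utility=(0.75, 0.0, 0.0),
        )
    )
    return KnownAnswer(
        name="flat_utility",
        parameters=params,
        strategy=Strategy.STOP_AT_CONCEPTION,
        expected_cost=0.0,
        expected_qaly=33 * 0.75 / 12,
    )


def _fixture_pure_drug() -> KnownAnswer:
    # only originator drug costs, stop at conception, undiscounted:
    # cost = 6 cycles x (1130 + 223) = 8118
    params = _degenerate_base()
    params = params.replace(
        drug=replace(
            params.drug,
            acquisition_cost_per_cycle=1130.0,
            administration_cost_per_cycle=223.0,
        )
    )
    return KnownAnswer(
        name="pure_drug",
        parameters=params,
        strategy=Strategy.STOP_AT_CONCEPTION,
        expected_cost=6 * (1130.0 + 223.0),
        expected_qaly=0.0,
    )


_FIXTURES = {
    "null_model": _fixture_null,
    "flat_utility": _fixture_flat_utility,
    "pure_drug": _fixture_pure_drug,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def known_answer_fixture(name: str) -> KnownAnswer:
    """A registered degenerate fixture with its analytically expected totals."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {', '.join(FIXTURE_NAMES)}"
        ) from None
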