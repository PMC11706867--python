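"""Model inputs for the natalizumab-in-pregnancy cost-effectiveness model.

Every quantity the Markov cohort model consumes lives here as a validated,
frozen domain type: the phase schedule (12 months pre-conception, 9 months
of pregnancy, 12 months post-pregnancy), annualised relapse rates per
strategy and phase, EDSS progression proportions, the banded EDSS structure
(occupancy, utilities, annual level costs), relapse economics, drug
economics, and the economic settings (discounting, willingness-to-pay,
PSA configuration).

Parameter sets load from a flat YAML dialect with one section per domain
type; any omitted field falls back to the packaged base-case value.  A
writer emits the same dialect so a resolved parameter set can be logged
for provenance and round-tripped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Strategy",
    "Phase",
    "REFERENCE_STRATEGY",
    "PRICE_VARIANTS",
    "Interval",
    "PhaseSchedule",
    "RelapseRateSet",
    "ProgressionInputs",
    "EdssStructure",
    "RelapseEconomics",
    "DrugEconomics",
    "EconomicSettings",
    "ModelParameters",
    "ParameterError",
    "arr_point_value",
    "progression_linear",
    "progression_log",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "load_edss_costs_csv",
]


class Strategy(str, enum.Enum):
    """The three natalizumab treatment strategies around pregnancy."""

    STOP_AT_CONCEPTION = "stop_at_conception"
    STOP_AFTER_FIRST_TRIMESTER = "stop_after_first_trimester"
    CONTINUE_THROUGH_PREGNANCY = "continue_through_pregnancy"

    @property
    def index(self) -> int:
        """1-based index used by the progression interpolation."""
        return list(Strategy).index(self) + 1


#: Reference strategy for all incremental comparisons.
REFERENCE_STRATEGY = Strategy.STOP_AT_CONCEPTION


class Phase(str, enum.Enum):
    PRE_CONCEPTION = "pre_conception"
    PREGNANCY = "pregnancy"
    POST_PREGNANCY = "post_pregnancy"


#: Per-cycle drug acquisition cost (GBP) for each price variant.
PRICE_VARIANTS: Mapping[str, float] = {
    "originator": 1130.0,
    "generic": 870.0,
    "biosimilar": 666.0,
}


class ParameterError(ValueError):
    """Raised when a parameter set violates one or more invariants.

    ``errors`` lists every violation with the offending field path, not
    just the first one found.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid parameters:\n  " + "\n  ".join(self.errors))


@dataclass(frozen=True)
class Interval:
    """Closed interval [low, high]; point values have low == high."""

    low: float
    high: float

    @property
    def midpoint(self) -> float:
        return arr_point_value(self)

    @classmethod
    def coerce(cls, value) -> "Interval":
        if isinstance(value, Interval):
            return value
        if isinstance(value, (int, float)):
            return cls(float(value), float(value))
        low, high = value
        return cls(float(low), float(high))


def arr_point_value(interval: Interval | Sequence[float] | float) -> float:
    """Reduce an annualised-relapse-rate interval to its midpoint.

    Printed relapse rates are ranges (e.g. 0.5-0.6); the deterministic
    base case uses the symmetric point value (low + high) / 2.  The PSA
    explores the surrounding range.
    """
    iv = Interval.coerce(interval)
    if iv.low > iv.high:
        raise ValueError(f"reversed interval [{iv.low}, {iv.high}]")
    if iv.low < 0:
        raise ValueError(f"negative rate interval [{iv.low}, {iv.high}]")
    return 0.5 * (iv.low + iv.high)


def progression_linear(index: int, slope: float = -4.58, intercept: float = 25.63) -> float:
    """EDSS-progression percentage from the linear interpolation y = slope*x + intercept.

    ``index`` is the 1-based strategy index (1 = stop at conception,
    2 = stop after first trimester, 3 = continue through pregnancy).
    Evaluated at x = 1, 2, 3 the default line returns 21.05, 16.47 and
    11.89 percent, matching the tabulated progression proportions to
    rounding.
    """
    if index not in (1, 2, 3):
        raise ValueError(f"strategy index must be 1, 2 or 3, got {index}")
    return slope * index + intercept


def progression_log(
    anchor1: tuple[float, float], anchor2: tuple[float, float], index: float
) -> float:
    """EDSS-progression percentage from a logarithmic fit y = a*ln(x) + b.

    Fits through two (index, percent) anchors and evaluates at ``index``.
    Used by the scenario analysis that replaces the linear interpolation
    with a logarithmic one.
    """
    (x1, y1), (x2, y2) = anchor1, anchor2
    if x1 <= 0 or x2 <= 0 or index <= 0:
        raise ValueError("indices must be positive for a logarithmic fit")
    if x1 == x2:
        raise ValueError("anchor indices coincide")
    a = (y2 - y1) / (math.log(x2) - math.log(x1))
    b = y1 - a * math.log(x1)
    return a * math.log(index) + b


@dataclass(frozen=True)
class PhaseSchedule:
    """Monthly-cycle phase layout: pre-conception, pregnancy, post-pregnancy."""

    pre_conception_months: int = 12
    pregnancy_months: int = 9
    post_pregnancy_months: int = 12

    @property
    def horizon(self) -> int:
        """Total model horizon in months (33 by default)."""
        return (
            self.pre_conception_months
            + self.pregnancy_months
            + self.post_pregnancy_months
        )

    def validate(self, path: str = "schedule") -> list[str]:
        errors = []
        for name in ("pre_conception_months", "pregnancy_months", "post_pregnancy_months"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                errors.append(f"{path}.{name}: must be a positive integer, got {v!r}")
        return errors


@dataclass(frozen=True)
class RelapseRateSet:
    """Annualised relapse rate (events per person-year) per strategy and phase."""

    rates: Mapping[Strategy, Mapping[Phase, Interval]]

    def interval(self, strategy: Strategy, phase: Phase) -> Interval:
        return self.rates[strategy][phase]

    def midpoint(self, strategy: Strategy, phase: Phase) -> float:
        return self.rates[strategy][phase].midpoint

    def validate(self, path: str = "relapse_rates") -> list[str]:
        errors = []
        for s in Strategy:
            for p in Phase:
                try:
                    iv = self.rates[s][p]
                except KeyError:
                    errors.append(f"{path}.{s.value}.{p.value}: missing entry")
                    continue
                if iv.low < 0:
                    errors.append(f"{path}.{s.value}.{p.value}: low {iv.low} < 0")
                if iv.low > iv.high:
                    errors.append(
                        f"{path}.{s.value}.{p.value}: reversed interval [{iv.low}, {iv.high}]"
                    )
        return errors


@dataclass(frozen=True)
class ProgressionInputs:
    """Horizon-level EDSS-band progression proportions and the interpolation line."""

    proportions: Mapping[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.STOP_AT_CONCEPTION: 0.21,
            Strategy.STOP_AFTER_FIRST_TRIMESTER: 0.16,
            Strategy.CONTINUE_THROUGH_PREGNANCY: 0.12,
        }
    )
    interpolation_slope: float = -4.58
    interpolation_intercept: float = 25.63

    def linear(self, strategy: Strategy) -> float:
        """Interpolated progression percentage for a strategy."""
        return progression_linear(
            strategy.index, self.interpolation_slope, self.interpolation_intercept
        )

    def validate(self, path: str = "progression") -> list[str]:
        errors = []
        for s in Strategy:
            v = self.proportions.get(s)
            if v is None:
                errors.append(f"{path}.proportions.{s.value}: missing entry")
            elif not 0 <= v <= 1:
                errors.append(f"{path}.proportions.{s.value}: {v} outside [0, 1]")
        return errors


BAND_LABELS = ("0-1", "2-3", "4+")


@dataclass(frozen=True)
class EdssStructure:
    """Banded EDSS disability structure of the cohort.

    The cohort is tracked in three EDSS bands (0-1, 2-3, 4+).  Annual
    direct costs are priced per individual EDSS level 0-9; band costs are
    the unweighted mean of the member levels, with the level range backing
    each band exposed (``band_level_ranges``) because the aggregation of
    the open-ended 4+ band is a modelling choice.

    The printed baseline occupancy sums to 0.954; by default the residual
    0.046 is carried as an unclassified stratum that accrues no cost and
    no utility, with ``renormalise=True`` instead scaling occupancy to the
    full simplex.
    """

    baseline_occupancy: tuple[float, float, float] = (0.539, 0.356, 0.059)
    band_utility: tuple[float, float, float] = (0.88, 0.75, 0.43)
    level_costs: tuple[float, ...] = (
        488.0, 887.0, 4611.0, 3656.0, 3474.0, 4850.0, 9602.0, 15412.0, 27786.0, 35545.0,
    )
    band_level_ranges: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 9))
    renormalise: bool = False

    def band_costs(self) -> tuple[float, ...]:
        """Annual cost per band: unweighted mean of member level costs."""
        out = []
        for lo, hi in self.band_level_ranges:
            members = self.level_costs[lo : hi + 1]
            out.append(sum(members) / len(members))
        return tuple(out)

    def occupancy_vector(self) -> tuple[float, ...]:
        """Initial band occupancy as simulated (renormalised if configured)."""
        total = sum(self.baseline_occupancy)
        if self.renormalise:
            return tuple(o / total for o in self.baseline_occupancy)
        return tuple(self.baseline_occupancy)

    @property
    def unclassified(self) -> float:
        """Cohort fraction outside the bands (0 when renormalising)."""
        if self.renormalise:
            return 0.0
        return max(0.0, 1.0 - sum(self.baseline_occupancy))

    def validate(self, path: str = "edss") -> list[str]:
        errors = []
        if len(self.baseline_occupancy) != len(BAND_LABELS):
            errors.append(f"{path}.baseline_occupancy: expected {len(BAND_LABELS)} bands")
        for i, o in enumerate(self.baseline_occupancy):
            if not 0 <= o <= 1:
                errors.append(f"{path}.baseline_occupancy[{i}]: {o} outside [0, 1]")
        if sum(self.baseline_occupancy) > 1 + 1e-9:
            errors.append(
                f"{path}.baseline_occupancy: sum {sum(self.baseline_occupancy):.4f} exceeds 1"
            )
        for i, u in enumerate(self.band_utility):
            if not 0 <= u <= 1:
                errors.append(f"{path}.band_utility[{i}]: {u} outside [0, 1]")
        for i, c in enumerate(self.level_costs):
            if c < 0:
                errors.append(f"{path}.level_costs[{i}]: {c} negative")
        for j, (lo, hi) in enumerate(self.band_level_ranges):
            if not (0 <= lo <= hi < len(self.level_costs)):
                errors.append(
                    f"{path}.band_level_ranges[{j}]: ({lo}, {hi}) outside level ladder"
                )
        return errors


@dataclass(frozen=True)
class RelapseEconomics:
    """Per-event QALY decrement and direct cost of an MS relapse."""

    disutility_per_relapse: float = 0.07
    cost_per_relapse: float = 1623.0

    def validate(self, path: str = "relapse_economics") -> list[str]:
        errors = []
        if self.disutility_per_relapse < 0:
            errors.append(f"{path}.disutility_per_relapse: negative")
        if self.cost_per_relapse < 0:
            errors.append(f"{path}.cost_per_relapse: negative")
        return errors


@dataclass(frozen=True)
class DrugEconomics:
    """Natalizumab acquisition/administration costs and per-strategy cycle totals.

    ``total_drug_cycles`` is the number of 4-weekly administrations over
    the 33-month horizon per strategy (fractional cycles allowed); the
    defaults 6 / 6.75 / 8.25 correspond to 24, 27 and 33 on-treatment
    months at one cycle per 4 weeks.
    """

    price_variant: str = "originator"
    acquisition_cost_per_cycle: float = 1130.0
    administration_cost_per_cycle: float = 223.0
    total_drug_cycles: Mapping[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.STOP_AT_CONCEPTION: 6.0,
            Strategy.STOP_AFTER_FIRST_TRIMESTER: 6.75,
            Strategy.CONTINUE_THROUGH_PREGNANCY: 8.25,
        }
    )

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "DrugEconomics":
        """Drug economics with the acquisition price of a named variant."""
        if variant not in PRICE_VARIANTS:
            raise ValueError(
                f"unknown price variant {variant!r}; expected one of {sorted(PRICE_VARIANTS)}"
            )
        return cls(
            price_variant=variant,
            acquisition_cost_per_cycle=PRICE_VARIANTS[variant],
            **kwargs,
        )

    def validate(self, path: str = "drug") -> list[str]:
        errors = []
        if self.acquisition_cost_per_cycle < 0:
            errors.append(f"{path}.acquisition_cost_per_cycle: negative")
        if self.administration_cost_per_cycle < 0:
            errors.append(f"{path}.administration_cost_per_cycle: negative")
        cycles = {}
        for s in Strategy:
            v = self.total_drug_cycles.get(s)
            if v is None:
                errors.append(f"{path}.total_drug_cycles.{s.value}: missing entry")
            elif v < 0:
                errors.append(f"{path}.total_drug_cycles.{s.value}: negative")
            else:
                cycles[s] = v
        if len(cycles) == 3 and not (
            cycles[Strategy.CONTINUE_THROUGH_PREGNANCY]
            >= cycles[Strategy.STOP_AFTER_FIRST_TRIMESTER]
            >= cycles[Strategy.STOP_AT_CONCEPTION]
        ):
            errors.append(
                f"{path}.total_drug_cycles: expected continue >= stop_after_first_trimester"
                " >= stop_at_conception"
            )
        return errors


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting, decision threshold and PSA configuration."""

    annual_discount_rate: float = 0.035
    wtp_threshold: float = 20000.0
    psa_draws: int = 1000
    psa_range: float = 0.20

    def validate(self, path: str = "settings") -> list[str]:
        errors = []
        if not 0 <= self.annual_discount_rate < 1:
            errors.append(f"{path}.annual_discount_rate: {self.annual_discount_rate} outside [0, 1)")
        if self.wtp_threshold <= 0:
            errors.append(f"{path}.wtp_threshold: must be positive")
        if self.psa_draws < 1:
            errors.append(f"{path}.psa_draws: must be >= 1")
        if not 0 <= self.psa_range < 1:
            errors.append(f"{path}.psa_range: {self.psa_range} outside [0, 1)")
        return errors


@dataclass(frozen=True)
class ModelParameters:
    """The full input set for one model run."""

    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    relapse_rates: RelapseRateSet = None  # type: ignore[assignment]
    progression: ProgressionInputs = field(default_factory=ProgressionInputs)
    edss: EdssStructure = field(default_factory=EdssStructure)
    relapse_econ: RelapseEconomics = field(default_factory=RelapseEconomics)
    drug: DrugEconomics = field(default_factory=DrugEconomics)
    settings: EconomicSettings = field(default_factory=EconomicSettings)

    def validate(self) -> None:
        """Check every component invariant; raise ParameterError listing all failures."""
        errors: list[str] = []
        errors += self.schedule.validate()
        errors += self.relapse_rates.validate()
        errors += self.progression.validate()
        errors += self.edss.validate()
        errors += self.relapse_econ.validate()
        errors += self.drug.validate()
        errors += self.settings.validate()
        if errors:
            raise ParameterError(errors)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Configuration I/O


def _default_relapse_rates() -> RelapseRateSet:
    iv = Interval
    return RelapseRateSet(
        rates={
            Strategy.STOP_AT_CONCEPTION: {
                Phase.PRE_CONCEPTION: iv(0.29, 0.29),
                Phase.PREGNANCY: iv(0.5, 0.6),
                Phase.POST_PREGNANCY: iv(0.4, 0.9),
            },
            Strategy.STOP_AFTER_FIRST_TRIMESTER: {
                Phase.PRE_CONCEPTION: iv(0.29, 0.29),
                Phase.PREGNANCY: iv(0.2, 0.5),
                Phase.POST_PREGNANCY: iv(0.3, 1.0),
            },
            Strategy.CONTINUE_THROUGH_PREGNANCY: {
                Phase.PRE_CONCEPTION: iv(0.21, 0.21),
                Phase.PREGNANCY: iv(0.2, 0.2),
                Phase.POST_PREGNANCY: iv(0.2, 0.6),
            },
        }
    )


def _params_to_dict(params: ModelParameters) -> dict:
    def iv_out(iv: Interval):
        return iv.low if iv.low == iv.high else [iv.low, iv.high]

    return {
        "schedule": {
            "pre_conception_months": params.schedule.pre_conception_months,
            "pregnancy_months": params.schedule.pregnancy_months,
            "post_pregnancy_months": params.schedule.post_pregnancy_months,
        },
        "relapse_rates": {
            s.value: {p.value: iv_out(params.relapse_rates.rates[s][p]) for p in Phase}
            for s in Strategy
        },
        "progression": {
            "proportions": {
                s.value: params.progression.proportions[s] for s in Strategy
            },
            "interpolation_slope": params.progression.interpolation_slope,
            "interpolation_intercept": params.progression.interpolation_intercept,
        },
        "edss": {
            "baseline_occupancy": list(params.edss.baseline_occupancy),
            "band_utility": list(params.edss.band_utility),
            "level_costs": list(params.edss.level_costs),
            "band_level_ranges": [list(r) for r in params.edss.band_level_ranges],
            "renormalise": params.edss.renormalise,
        },
        "relapse_economics": {
            "disutility_per_relapse": params.relapse_econ.disutility_per_relapse,
            "cost_per_relapse": params.relapse_econ.cost_per_relapse,
        },
        "drug": {
            "price_variant": params.drug.price_variant,
            "acquisition_cost_per_cycle": params.drug.acquisition_cost_per_cycle,
            "administration_cost_per_cycle": params.drug.administration_cost_per_cycle,
            "total_drug_cycles": {
                s.value: params.drug.total_drug_cycles[s] for s in Strategy
            },
        },
        "settings": {
            "annual_discount_rate": params.settings.annual_discount_rate,
            "wtp_threshold": params.settings.wtp_threshold,
            "psa_draws": params.settings.psa_draws,
            "psa_range": params.settings.psa_range,
        },
    }


def _params_from_dict(data: dict) -> ModelParameters:
    sched = data["schedule"]
    rates = {
        s: {p: Interval.coerce(data["relapse_rates"][s.value][p.value]) for p in Phase}
        for s in Strategy
    }
    prog = data["progression"]
    edss = data["edss"]
    rel = data["relapse_economics"]
    drug = data["drug"]
    settings = data["settings"]
    return ModelParameters(
        schedule=PhaseSchedule(
            pre_conception_months=sched["pre_conception_months"],
            pregnancy_months=sched["pregnancy_months"],
            post_pregnancy_months=sched["post_pregnancy_months"],
        ),
        relapse_rates=RelapseRateSet(rates=rates),
        progression=ProgressionInputs(
            proportions={s: float(prog["proportions"][s.value]) for s in Strategy},
            interpolation_slope=float(prog["interpolation_slope"]),
            interpolation_intercept=float(prog["interpolation_intercept"]),
        ),
        edss=EdssStructure(
            baseline_occupancy=tuple(float(x) for x in edss["baseline_occupancy"]),
            band_utility=tuple(float(x) for x in edss["band_utility"]),
            level_costs=tuple(float(x) for x in edss["level_costs"]),
            band_level_ranges=tuple(
                (int(lo), int(hi)) for lo, hi in edss["band_level_ranges"]
            ),
            renormalise=bool(edss["renormalise"]),
        ),
        relapse_econ=RelapseEconomics(
            disutility_per_relapse=float(rel["disutility_per_relapse"]),
            cost_per_relapse=float(rel["cost_per_relapse"]),
        ),
        drug=DrugEconomics(
            price_variant=str(drug["price_variant"]),
            acquisition_cost_per_cycle=float(drug["acquisition_cost_per_cycle"]),
            administration_cost_per_cycle=float(drug["administration_cost_per_cycle"]),
            total_drug_cycles={
                s: float(drug["total_drug_cycles"][s.value]) for s in Strategy
            },
        ),
        settings=EconomicSettings(
            annual_discount_rate=float(settings["annual_discount_rate"]),
            wtp_threshold=float(settings["wtp_threshold"]),
            psa_draws=int(settings["psa_draws"]),
            psa_range=float(settings["psa_range"]),
        ),
    )


def default_parameters() -> ModelParameters:
    """The packaged base-case parameter set (originator prices)."""
    ref = resources.files("natcea.data").joinpath("base_case.yaml")
    with ref.open() as fh:
        data = yaml.safe_load(fh)
    params = _params_from_dict(data)
    params.validate()
    return params


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_parameters(config_path: str | Path | None = None) -> ModelParameters:
    """Load a parameter set from a YAML configuration file.

    Any field omitted from the file defaults to the packaged base-case
    value.  ``None`` loads the packaged defaults themselves.  Raises
    ``ParameterError`` listing every violated invariant.
    """
    base = _params_to_dict(default_parameters())
    if config_path is None:
        data = base
    else:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"parameter file not found: {path}")
        with open(path) as fh:
            try:
                override = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ParameterError([f"{path}: malformed YAML: {exc}"]) from exc
        if override is None:
            override = {}
        if not isinstance(override, dict):
            raise ParameterError([f"{path}: top level must be a mapping"])
        data = _deep_merge(base, override)
    try:
        params = _params_from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError([f"malformed configuration: {exc!r}"]) from exc
    params.validate()
    return params


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set in the configuration dialect (round-trippable)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def load_edss_costs_csv(path: str | Path) -> tuple[float, ...]:
    """Read an EDSS level-cost override table (columns: edss_level, annual_cost_gbp)."""
    import pandas as pd

    table = pd.read_csv(path)
    missing = {"edss_level", "annual_cost_gbp"} - set(table.columns)
    if missing:
        raise ParameterError([f"{path}: missing columns {sorted(missing)}"])
    table = table.sort_values("edss_level")
    levels = table["edss_level"].tolist()
    if levels != list(range(len(levels))):
        raise ParameterError([f"{path}: edss_level must enumerate 0..{len(levels) - 1}"])
    return tuple(float(c) for c in table["annual_cost_gbp"])
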