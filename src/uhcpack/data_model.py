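"""Domain types and input/output for benefit-package analysis.

The analysis consumes a table of health interventions, each described by
cumulative per-capita annual cost (2000 international dollars) and cumulative
per-capita annual DALYs averted at three coverage anchors (50%, 80% and 95%
of the incident population), together with the size of the incident
population.  Per-capita here means per member of the *incident* population of
the intervention, not per member of the general population: that reading is
the only one under which the package totals are mutually consistent (for
example, tuberculosis DOTS averts 0.130 DALYs per incident case at 95%
coverage, and 0.130 x 112,918 incident cases reproduces the roughly 14.7
thousand DALYs the intervention contributes to the optimal package).  This
interpretation is asserted by a consistency test in the suite.

Coverage fractions are stored as reals in [0, 1] throughout; percent
formatting happens only in the reporting layer.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

COVERAGE_ANCHORS: tuple[float, ...] = (0.50, 0.80, 0.95)

CSV_COLUMNS: tuple[str, ...] = (
    "id",
    "name",
    "incident_population",
    "population_definition",
    "cost_50",
    "cost_80",
    "cost_95",
    "dalys_50",
    "dalys_80",
    "dalys_95",
)

SCENARIOS: tuple[str, ...] = ("variable_coverage", "equity_weighted", "all_or_nothing")

#: CLI-friendly aliases for the three analysis scenarios.
SCENARIO_ALIASES: dict[str, str] = {
    "1": "variable_coverage",
    "2": "equity_weighted",
    "3": "all_or_nothing",
    "variable_coverage": "variable_coverage",
    "equity_weighted": "equity_weighted",
    "all_or_nothing": "all_or_nothing",
}


class UhcpackError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(UhcpackError):
    """An input file does not match the documented schema."""


class ParseError(UhcpackError):
    """A cell of an input file could not be parsed."""


class ValidationError(UhcpackError):
    """An input value violates a domain invariant."""


class ConfigError(UhcpackError):
    """An analysis configuration is inconsistent."""


@dataclass(frozen=True)
class InterventionRecord:
    """One intervention's coverage anchors and incident population.

    ``anchor_cost`` and ``anchor_benefit`` map coverage fractions
    (0.50, 0.80, 0.95) to cumulative annual per-capita cost (2000 Int$) and
    cumulative annual per-capita DALYs averted, per member of the incident
    population.
    """

    id: str
    name: str
    incident_population: int
    population_definition: str
    anchor_cost: Mapping[float, float]
    anchor_benefit: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.incident_population <= 0:
            raise ValidationError(
                f"{self.id}: incident_population must be positive, "
                f"got {self.incident_population}"
            )
        for label, mapping in (("cost", self.anchor_cost), ("benefit", self.anchor_benefit)):
            missing = [a for a in COVERAGE_ANCHORS if a not in mapping]
            if missing:
                raise ValidationError(
                    f"{self.id}: {label} anchors missing coverage levels {missing}"
                )
            values = [mapping[a] for a in COVERAGE_ANCHORS]
            if any(v < 0 for v in values):
                raise ValidationError(f"{self.id}: negative {label} anchor value")
            if not all(v1 <= v2 for v1, v2 in zip(values, values[1:])):
                raise ValidationError(
                    f"{self.id}: cumulative {label} must be non-decreasing in "
                    f"coverage, got {values}"
                )

    @property
    def cost_anchors(self) -> tuple[float, float, float]:
        return tuple(self.anchor_cost[a] for a in COVERAGE_ANCHORS)

    @property
    def benefit_anchors(self) -> tuple[float, float, float]:
        return tuple(self.anchor_benefit[a] for a in COVERAGE_ANCHORS)


@dataclass(frozen=True)
class EquityWeightSchedule:
    """Weights attached to health benefits by coverage band.

    Each band is a half-open interval ``(lo, hi]`` of coverage with a weight
    >= 1; coverage outside every band carries ``default_weight`` (1).  The
    default schedule weights the hardest-to-reach decile of the population
    (coverage in (0.9, 1.0]) by 4 and the penultimate decile (0.8, 0.9] by 2,
    reflecting the assumption that the people reached last are the most
    disadvantaged.
    """

    bands: tuple[tuple[float, float, float], ...] = ()
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.default_weight < 1.0:
            raise ValidationError("default_weight must be >= 1")
        prev_hi = 0.0
        for lo, hi, w in sorted(self.bands):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(f"weight band ({lo}, {hi}] outside (0, 1]")
            if w < 1.0:
                raise ValidationError(f"weight {w} in band ({lo}, {hi}] is < 1")
            if lo < prev_hi - 1e-12:
                raise ValidationError("weight bands overlap")
            prev_hi = hi
        object.__setattr__(self, "bands", tuple(sorted(self.bands)))

    @classmethod
    def flat(cls) -> "EquityWeightSchedule":
        """A schedule of all-1 weights (no equity weighting)."""
        return cls(bands=())

    @classmethod
    def default(cls) -> "EquityWeightSchedule":
        """Weight 4 on the last coverage decile, 2 on the penultimate."""
        return cls(bands=((0.8, 0.9, 2.0), (0.9, 1.0, 4.0)))

    def weight_at(self, theta: float) -> float:
        """Weight applied to benefits accruing at coverage ``theta``.

        Bands are half-open ``(lo, hi]``.
        """
        for lo, hi, w in self.bands:
            if lo < theta <= hi:
                return w
        return self.default_weight

    def boundaries(self) -> tuple[float, ...]:
        """Sorted interior cut points at which the weight may change."""
        pts: set[float] = set()
        for lo, hi, _ in self.bands:
            pts.add(lo)
            pts.add(hi)
        return tuple(sorted(pts))

    def is_flat(self) -> bool:
        return all(w == self.default_weight for _, _, w in self.bands)

    def to_json_obj(self) -> list[dict[str, float]]:
        return [{"lo": lo, "hi": hi, "weight": w} for lo, hi, w in self.bands]

    @classmethod
    def from_json_obj(cls, obj: Iterable[Mapping[str, float]]) -> "EquityWeightSchedule":
        return cls(bands=tuple((float(b["lo"]), float(b["hi"]), float(b["weight"])) for b in obj))


def _check_grid(grid_floor: float, grid_step: float) -> int:
    """Number of steps from ``grid_floor`` to 1.0; raises if not exact."""
    if not (0.0 < grid_floor < 1.0):
        raise ConfigError(f"grid_floor {grid_floor} outside (0, 1)")
    if grid_step <= 0:
        raise ConfigError(f"grid_step {grid_step} must be positive")
    k = round((1.0 - grid_floor) / grid_step)
    if k < 1 or abs(grid_floor + k * grid_step - 1.0) > 1e-9:
        raise ConfigError(
            f"coverage grid {grid_floor} + k*{grid_step} never lands exactly on 1.0"
        )
    return k


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one optimization run.

    ``budget`` is the discretionary annual budget in 2015 US$;
    ``conversion_factor`` converts 2000 Int$ costs into 2015 US$ and is a
    user decision (no constant is baked in; see ``calibrate_conversion``).
    ``total_population`` is carried for provenance only: all arithmetic is in
    terms of each intervention's incident population.
    """

    budget: float = 15_000_000.0
    conversion_factor: float = 1.0
    total_population: int = 25_000_000
    grid_floor: float = 0.50
    grid_step: float = 0.05
    scenario: str = "variable_coverage"
    weights: EquityWeightSchedule = field(default_factory=EquityWeightSchedule.default)
    all_or_nothing_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ConfigError(f"budget must be non-negative, got {self.budget}")
        if self.conversion_factor <= 0:
            raise ConfigError("conversion_factor must be positive")
        _check_grid(self.grid_floor, self.grid_step)
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if not (0.0 < self.all_or_nothing_level <= 1.0):
            raise ConfigError("all_or_nothing_level outside (0, 1]")

    @property
    def grid(self) -> tuple[float, ...]:
        """Coverage levels 0, floor, floor+step, ..., 1.0."""
        k = _check_grid(self.grid_floor, self.grid_step)
        levels = [0.0] + [
            round(self.grid_floor + i * self.grid_step, 9) for i in range(k + 1)
        ]
        levels[-1] = 1.0
        return tuple(levels)

    def with_(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_json_obj(self) -> dict:
        return {
            "budget": self.budget,
            "conversion_factor": self.conversion_factor,
            "total_population": self.total_population,
            "grid_floor": self.grid_floor,
            "grid_step": self.grid_step,
            "scenario": self.scenario,
            "weights": self.weights.to_json_obj(),
            "all_or_nothing_level": self.all_or_nothing_level,
            "seed": self.seed,
        }


def _parse_number(raw: str, row: int, column: str, kind=float):
    try:
        return kind(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}, column {column!r}: could not parse {raw!r} as {kind.__name__}"
        ) from None


def _records_from_reader(reader: csv.DictReader, source: str) -> list[InterventionRecord]:
    if reader.fieldnames is None:
        raise SchemaError(f"{source}: empty file")
    missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(reader, start=2):
        pop = _parse_number(row["incident_population"], i, "incident_population", int)
        cost = {
            a: _parse_number(row[f"cost_{int(a * 100)}"], i, f"cost_{int(a * 100)}")
            for a in COVERAGE_ANCHORS
        }
        ben = {
            a: _parse_number(row[f"dalys_{int(a * 100)}"], i, f"dalys_{int(a * 100)}")
            for a in COVERAGE_ANCHORS
        }
        records.append(
            InterventionRecord(
                id=row["id"],
                name=row["name"],
                incident_population=pop,
                population_definition=row["population_definition"],
                anchor_cost=cost,
                anchor_benefit=ben,
            )
        )
    return records


def load_interventions(path: str | Path) -> list[InterventionRecord]:
    """Read intervention records from a CSV file.

    The header must contain the documented columns; row order is preserved
    and later used for deterministic tie-breaking.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        return _records_from_reader(csv.DictReader(fh), str(path))


def write_interventions(records: Sequence[InterventionRecord], path: str | Path) -> None:
    """Write records to CSV in the documented schema (round-trips losslessly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.name,
                    r.incident_population,
                    r.population_definition,
                    *(format(r.anchor_cost[a], "g") for a in COVERAGE_ANCHORS),
                    *(format(r.anchor_benefit[a], "g") for a in COVERAGE_ANCHORS),
                ]
            )


def fixture_bytes() -> bytes:
    """Raw bytes of the packaged WHO-CHOICE AFR-E fixture (for provenance)."""
    return (
        resources.files("uhcpack").joinpath("data/who_choice_afr_e.csv").read_bytes()
    )


def builtin_fixture() -> list[InterventionRecord]:
    """The packaged WHO-CHOICE AFR-E table of 16 interventions.

    Costs are cumulative annual 2000 Int$ per member of the incident
    population; benefits are cumulative annual DALYs averted per member of
    the incident population; both at 50%, 80% and 95% coverage.
    """
    text = fixture_bytes().decode("utf-8")
    return _records_from_reader(csv.DictReader(text.splitlines()), "builtin fixture")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from JSON, applying defaults."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from None
    return config_from_json_obj(obj)


def config_from_json_obj(obj: Mapping) -> AnalysisConfig:
    if not isinstance(obj, Mapping):
        raise ConfigError("configuration JSON must be an object")
    kwargs: dict = {}
    simple = (
        "budget",
        "conversion_factor",
        "total_population",
        "grid_floor",
        "grid_step",
        "all_or_nothing_level",
        "seed",
    )
    for key in simple:
        if key in obj:
            kwargs[key] = obj[key]
    if "scenario" in obj:
        scenario = SCENARIO_ALIASES.get(str(obj["scenario"]))
        if scenario is None:
            raise ConfigError(f"unknown scenario {obj['scenario']!r}")
        kwargs["scenario"] = scenario
    if "weights" in obj:
        kwargs["weights"] = EquityWeightSchedule.from_json_obj(obj["weights"])
    unknown = set(obj) - set(simple) - {"scenario", "weights"}
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    return AnalysisConfig(**kwargs)
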