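"""Synthetic instances and independent oracles.

The generator samples per-capita quadratic cost and benefit curves directly
(base value at the grid floor, slope, curvature), evaluates them at the
50/80/95% anchors, and emits records shaped exactly like the real input
table.  Sampling the curve and evaluating it at the anchors guarantees that
three-point interpolation recovers the sampled coefficients exactly, and
monotone anchors hold by construction.  Defaults mirror the real data:
convex costs (scale-up gets dearer), weakly concave benefits, populations
and cost scales spanning two orders of magnitude.

``brute_force_optimum`` enumerates every coverage vector on the grid -
optionally topped up with a single fractional step - and is the independent
check on the league-table heuristic.  Note the heuristic is exact for the
one-fractional-step relaxation only when its underspend-reallocation loop
terminates without post-stop admissions; instances where the loop does admit
extra whole steps are genuine counterexamples and are reported, not hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import (
    COVERAGE_ANCHORS,
    AnalysisConfig,
    EquityWeightSchedule,
    InterventionRecord,
    UhcpackError,
)
from .optimizer import Ladder, build_ladders, solve_scenario

__all__ = [
    "SyntheticSpec",
    "generate_instance",
    "brute_force_optimum",
    "BruteForceResult",
    "parameter_recovery_suite",
]

MAX_ORACLE_INTERVENTIONS = 6
MAX_ORACLE_LEVELS = 12


class SyntheticSpecError(UhcpackError):
    pass


class OracleSizeError(UhcpackError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for synthetic intervention tables.

    Curvatures are relative to the base (grid-floor) value, so a cost
    curvature of 1.5 means the quadratic term at full coverage is up to 1.5x
    the 50%-coverage cost.  ``anchor_noise`` multiplies anchors by
    ``1 + noise * N(0,1)`` and then restores monotonicity by a running
    maximum (0 by default: the curves are exact).
    """

    n_interventions: int = 4
    population_range: tuple[int, int] = (20_000, 5_000_000)
    base_cost_range: tuple[float, float] = (0.03, 1.0)
    cost_slope_range: tuple[float, float] = (0.1, 1.5)
    cost_curvature_range: tuple[float, float] = (0.0, 1.5)
    base_benefit_range: tuple[float, float] = (0.001, 0.1)
    benefit_slope_range: tuple[float, float] = (0.1, 1.0)
    benefit_curvature_range: tuple[float, float] = (-0.4, 0.0)
    anchor_noise: float = 0.0
    grid_floor: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interventions < 1:
            raise SyntheticSpecError("n_interventions must be >= 1")
        for name in (
            "population_range",
            "base_cost_range",
            "cost_slope_range",
            "cost_curvature_range",
            "base_benefit_range",
            "benefit_slope_range",
            "benefit_curvature_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SyntheticSpecError(f"{name}: empty range ({lo}, {hi})")
        if self.base_cost_range[0] <= 0 or self.base_benefit_range[0] <= 0:
            raise SyntheticSpecError("base cost/benefit must be positive")
        if self.cost_slope_range[0] < 0 or self.benefit_slope_range[0] < 0:
            raise SyntheticSpecError("slopes must be non-negative")
        if self.anchor_noise < 0:
            raise SyntheticSpecError("anchor_noise must be >= 0")


def _sample_curve(rng: np.random.Generator, base, slope_rng, curv_rng, floor):
    """Sample v(theta) = v_f + m (theta-f) + q (theta-f)^2, monotone on [f, 1]."""
    m = rng.uniform(*slope_rng) * base
    q = rng.uniform(*curv_rng) * base
    # monotone non-decreasing on [floor, 1]: derivative m + 2q(theta-floor) >= 0
    if q < 0.0:
        m = max(m, -2.0 * q * (1.0 - floor))
    return lambda theta: base + m * (theta - floor) + q * (theta - floor) ** 2


def generate_instance(spec: SyntheticSpec) -> list[InterventionRecord]:
    """Deterministically sample a synthetic intervention table."""
    rng = np.random.default_rng(spec.seed)
    floor = spec.grid_floor
    records: list[InterventionRecord] = []
    for i in range(spec.n_interventions):
        pop = int(rng.integers(spec.population_range[0], spec.population_range[1] + 1))
        cost_fn = _sample_curve(
            rng,
            rng.uniform(*spec.base_cost_range),
            spec.cost_slope_range,
            spec.cost_curvature_range,
            floor,
        )
        ben_fn = _sample_curve(
            rng,
            rng.uniform(*spec.base_benefit_range),
            spec.benefit_slope_range,
            spec.benefit_curvature_range,
            floor,
        )
        cost = np.array([cost_fn(t) for t in COVERAGE_ANCHORS])
        ben = np.array([ben_fn(t) for t in COVERAGE_ANCHORS])
        if spec.anchor_noise > 0.0:
            cost = cost * (1.0 + spec.anchor_noise * rng.standard_normal(3))
            ben = ben * (1.0 + spec.anchor_noise * rng.standard_normal(3))
            cost = np.maximum.accumulate(np.clip(cost, 0.0, None))
            ben = np.maximum.accumulate(np.clip(ben, 0.0, None))
        if np.any(cost < 0.0) or np.any(ben < 0.0):  # pragma: no cover - defensive
            raise SyntheticSpecError("sampled ranges produced negative anchors")
        records.append(
            InterventionRecord(
                id=f"synthetic_{i:02d}",
                name=f"Synthetic intervention {i:02d}",
                incident_population=pop,
                population_definition="synthetic incident population",
                anchor_cost=dict(zip(COVERAGE_ANCHORS, cost.tolist())),
                anchor_benefit=dict(zip(COVERAGE_ANCHORS, ben.tolist())),
            )
        )
    return records


# ---------------------------------------------------------------------------
# brute-force oracle


@dataclass(frozen=True)
class BruteForceResult:
    coverage: dict[str, float]
    total_cost: float
    total_benefit: float  # effective (weighted under the equity scenario)
    fractional_intervention_id: str | None = None
    fractional_coverage: float | None = None


def _level_tables(ladders: Sequence[Ladder], levels: Sequence[float]):
    """Cumulative cost / effective-benefit arrays per ladder at each level."""
    costs, benefits = [], []
    for ladder in ladders:
        c = [0.0]
        b = [0.0]
        for step in ladder.steps:
            c.append(c[-1] + step.delta_cost)
            b.append(b[-1] + step.effective_benefit)
        if len(c) != len(levels):  # pragma: no cover - defensive
            raise OracleSizeError("ladder does not match the level grid")
        costs.append(np.asarray(c))
        benefits.append(np.asarray(b))
    return costs, benefits


def brute_force_optimum(
    records: Sequence[InterventionRecord],
    config: AnalysisConfig,
    mode: str = "integral",
) -> BruteForceResult:
    """Exhaustive optimum over grid coverage vectors within the budget.

    ``integral`` enumerates pure grid vectors; ``divisible_last``
    additionally allows a single intervention one fractional step beyond its
    grid level (benefit linear in spend within the step), optimized in
    closed form for every vector.  Deterministic: ties resolve to the first
    vector in lexicographic level order.
    """
    if mode not in ("integral", "divisible_last"):
        raise UhcpackError(f"unknown oracle mode {mode!r}")
    ladders = build_ladders(records, config)
    if config.scenario == "all_or_nothing":
        levels: tuple[float, ...] = (0.0, config.all_or_nothing_level)
    else:
        levels = config.grid
    n = len(ladders)
    if n > MAX_ORACLE_INTERVENTIONS or len(levels) > MAX_ORACLE_LEVELS:
        raise OracleSizeError(
            f"instance ({n} interventions x {len(levels)} levels) exceeds the "
            f"enumeration bound ({MAX_ORACLE_INTERVENTIONS} x {MAX_ORACLE_LEVELS})"
        )
    costs, benefits = _level_tables(ladders, levels)
    L = len(levels)
    shape = (L,) * n
    idx = np.indices(shape, dtype=np.int8).reshape(n, -1)
    total_cost = np.zeros(idx.shape[1])
    total_ben = np.zeros(idx.shape[1])
    for i in range(n):
        total_cost += costs[i][idx[i]]
        total_ben += benefits[i][idx[i]]
    budget = config.budget
    feasible = total_cost <= budget * (1.0 + 1e-12)
    if not np.any(feasible):  # budget below zero-coverage cost cannot happen
        raise UhcpackError("no feasible coverage vector")

    if mode == "integral":
        score = np.where(feasible, total_ben, -np.inf)
        best = int(np.argmax(score))
        cov = {ladders[i].id: levels[int(idx[i, best])] for i in range(n)}
        return BruteForceResult(
            coverage=cov,
            total_cost=float(total_cost[best]),
            total_benefit=float(total_ben[best]),
        )

    leftover = np.where(feasible, budget - total_cost, 0.0)
    best_extra = np.zeros(idx.shape[1])
    best_frac_i = np.full(idx.shape[1], -1, dtype=np.int8)
    best_frac = np.zeros(idx.shape[1])
    for i in range(n):
        lv = idx[i].astype(np.int64)
        has_next = lv < L - 1
        nxt = np.minimum(lv + 1, L - 1)
        d_cost = costs[i][nxt] - costs[i][lv]
        d_ben = benefits[i][nxt] - benefits[i][lv]
        ok = has_next & (d_ben > 0.0) & (d_cost > 0.0)
        frac = np.zeros_like(d_cost)
        np.divide(leftover, d_cost, out=frac, where=ok)
        frac = np.minimum(frac, 1.0)
        extra = np.where(ok, frac * d_ben, 0.0)
        better = extra > best_extra + 1e-15
        best_extra = np.where(better, extra, best_extra)
        best_frac_i = np.where(better, np.int8(i), best_frac_i)
        best_frac = np.where(better, frac, best_frac)
    score = np.where(feasible, total_ben + best_extra, -np.inf)
    best = int(np.argmax(score))
    cov = {ladders[i].id: levels[int(idx[i, best])] for i in range(n)}
    frac_id = None
    frac_cov = None
    extra_spend = 0.0
    fi = int(best_frac_i[best])
    if fi >= 0 and best_extra[best] > 0.0:
        lv = int(idx[fi, best])
        frac_id = ladders[fi].id
        frac_cov = levels[lv] + float(best_frac[best]) * (levels[lv + 1] - levels[lv])
        cov[frac_id] = frac_cov
        extra_spend = float(best_frac[best]) * float(costs[fi][lv + 1] - costs[fi][lv])
    return BruteForceResult(
        coverage=cov,
        total_cost=float(total_cost[best]) + extra_spend,
        total_benefit=float(score[best]),
        fractional_intervention_id=frac_id,
        fractional_coverage=frac_cov,
    )


# ---------------------------------------------------------------------------
# property suite


def _effective_total(solution) -> float:
    return (
        solution.total_weighted_dalys
        if solution.scenario == "equity_weighted"
        else solution.total_dalys
    )


def _loop_was_clean(solution) -> bool:
    """True if the underspend loop admitted nothing after the initial fill.

    Under that condition (and a single-step terminal fraction) the heuristic
    coincides with the one-fractional-step optimum; otherwise it may fall
    short by design.
    """
    return not any(
        e["action"] == "admit" and e["pass"] > 0
        for e in solution.iteration_log
        if isinstance(e["pass"], int)
    )


def parameter_recovery_suite(
    seed: int,
    n_instances: int = 30,
    n_interventions: int = 4,
    budget_fraction_range: tuple[float, float] = (0.3, 0.7),
) -> dict:
    """Generate -> solve -> sweep, checking the optimizer's invariants.

    Hard invariants (any violation is an implementation bug and is reported
    as a *failure*): budget feasibility; identity of the equity scenario
    under all-1 weights with the unweighted scenario; scale invariance of
    the coverage vector; and, within enumeration bounds, exact agreement
    with the one-fractional-step enumeration optimum on instances where the
    underspend loop admitted nothing after the initial fill (under that
    condition the league-table procedure is provably optimal for that
    relaxation).

    Known limitations of the procedure itself are measured and reported as
    *diagnostics*, not failures: on instances where the reallocation loop
    does fire, the heuristic can fall below even the integral enumeration
    optimum (a large 0 -> 50% entry block gets crowded out by cheaper,
    less cost-effective steps), and consequently total health need not be
    monotone in the budget.  Both effects are genuine to the method; the
    report quantifies them so they are visible, never hidden.
    """
    rng = np.random.default_rng(seed)
    report: dict = {
        "seed": int(seed),
        "n_instances": int(n_instances),
        "checks": {},
        "failures": [],
        "counterexamples": [],
        "diagnostics": {"integral_gap_instances": [], "monotonicity_breaks": []},
        "oracle_status": "run" if n_interventions <= MAX_ORACLE_INTERVENTIONS else "skipped",
        "clean_loop_instances": 0,
    }

    def record_failure(kind: str, inst_seed: int, detail: str) -> None:
        report["failures"].append({"check": kind, "seed": inst_seed, "detail": detail})

    counts = {
        k: 0
        for k in (
            "feasibility",
            "weights_identity",
            "scale_invariance",
            "oracle_lower_bound",
            "oracle_equality",
        )
    }

    for k in range(n_instances):
        inst_seed = int((seed * 100_003 + 7919 * k + 1) % (2**31))
        spec = SyntheticSpec(n_interventions=n_interventions, seed=inst_seed)
        records = generate_instance(spec)
        frac = float(rng.uniform(*budget_fraction_range))
        probe = AnalysisConfig(budget=1.0, conversion_factor=1.0)
        full_cost = sum(L.total_cost for L in build_ladders(records, probe))
        config = AnalysisConfig(budget=frac * full_cost, conversion_factor=1.0)
        solution = solve_scenario(records, config)

        counts["feasibility"] += 1
        if solution.total_spend > config.budget * (1.0 + 1e-6):
            record_failure(
                "feasibility", inst_seed,
                f"spend {solution.total_spend} exceeds budget {config.budget}",
            )

        flat = config.with_(scenario="equity_weighted", weights=EquityWeightSchedule.flat())
        counts["weights_identity"] += 1
        if solve_scenario(records, flat).coverage_vector() != solution.coverage_vector():
            record_failure("weights_identity", inst_seed, "coverage vectors differ")

        scaled = config.with_(budget=config.budget * 3.0, conversion_factor=3.0)
        counts["scale_invariance"] += 1
        scaled_cov = solve_scenario(records, scaled).coverage_vector()
        if any(
            abs(scaled_cov[i] - c) > 1e-9 for i, c in solution.coverage_vector().items()
        ):
            record_failure("scale_invariance", inst_seed, "coverage vectors differ")

        if report["oracle_status"] == "run":
            integral = brute_force_optimum(records, config, "integral")
            divisible = brute_force_optimum(records, config, "divisible_last")
            achieved = _effective_total(solution)
            counts["oracle_lower_bound"] += 1
            if achieved < integral.total_benefit * (1.0 - 1e-9) - 1e-12:
                report["diagnostics"]["integral_gap_instances"].append(
                    {
                        "seed": inst_seed,
                        "budget": config.budget,
                        "greedy": achieved,
                        "integral_optimum": integral.total_benefit,
                    }
                )
            if _loop_was_clean(solution):
                report["clean_loop_instances"] += 1
                counts["oracle_equality"] += 1
                if abs(achieved - divisible.total_benefit) > 1e-6 * max(
                    1.0, divisible.total_benefit
                ):
                    record_failure(
                        "oracle_equality", inst_seed,
                        f"greedy {achieved} != divisible-last optimum "
                        f"{divisible.total_benefit}",
                    )
                    report["counterexamples"].append(
                        {"seed": inst_seed, "budget": config.budget}
                    )

    # budget sweep: monotonicity of total health in the budget (diagnostic)
    sweep_seed = int((seed * 100_003 + 1) % (2**31))
    records = generate_instance(SyntheticSpec(n_interventions=n_interventions, seed=sweep_seed))
    probe = AnalysisConfig(budget=1.0, conversion_factor=1.0)
    full_cost = sum(L.total_cost for L in build_ladders(records, probe))
    totals = []
    for frac in np.linspace(0.05, 1.1, 20):
        cfg = AnalysisConfig(budget=frac * full_cost, conversion_factor=1.0)
        totals.append(solve_scenario(records, cfg).total_dalys)
    for a, b in zip(totals, totals[1:]):
        if b < a - 1e-9 * max(1.0, a):
            report["diagnostics"]["monotonicity_breaks"].append(
                {"seed": sweep_seed, "totals": totals}
            )
            break

    report["checks"] = counts
    report["n_failures"] = len(report["failures"])
    report["passed"] = not report["failures"]
    return report
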