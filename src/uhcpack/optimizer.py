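"""Budget-constrained package optimization.

The solver implements a league-table procedure over the incremental coverage
alternatives of all interventions:

1. dominance elimination within each intervention (``alternatives`` module),
2. rank-and-fill: admit non-dominated alternatives in ascending ICER order
   until the next one no longer fits in the remaining budget,
3. an underspend-reallocation loop: drop alternatives whose cumulative
   additional cost from the current coverage exceeds the remaining budget,
   recompute ICERs incremental to current coverage (previously dominated
   steps re-enter here), re-apply dominance, re-rank and admit; repeat until
   no whole alternative is affordable; finally scale up fractionally the
   single next grid increment with the lowest ICER, with coverage and
   benefits advancing linearly in spend within that increment.

The ICER of the last (possibly fractional) increment is the empirical
marginal productivity of the discretionary budget - the league-table
analogue of the Lagrange multiplier on the budget constraint.

Three scenarios are supported: ``variable_coverage`` (ICERs on unweighted
DALYs), ``equity_weighted`` (ICERs on decile-weighted DALYs; both weighted
and unweighted totals are reported), and ``all_or_nothing`` (a single 0 ->
95% alternative per intervention with cost and benefit linear through the
origin, the terminal intervention still divisible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .alternatives import (
    IncrementalAlternative,
    apply_equity_weights,
    build_grid_alternatives,
    eliminate_dominated,
)
from .curves import CostBenefitCurve, fit_anchor_curve
from .data_model import AnalysisConfig, InterventionRecord, UhcpackError

__all__ = [
    "Ladder",
    "Solution",
    "InterventionOutcome",
    "build_ladders",
    "greedy_fill",
    "underspend_loop",
    "solve_scenario",
    "marginal_productivity",
    "calibrate_conversion",
    "CalibrationResult",
    "Landmark",
]

_EPS = 1e-9


class OptimizerError(UhcpackError):
    pass


class EmptySolutionError(OptimizerError):
    """Raised when a diagnostic is undefined because nothing was funded."""


class CalibrationError(OptimizerError):
    pass


# ---------------------------------------------------------------------------
# ladders


@dataclass(frozen=True)
class Ladder:
    """All raw (pre-dominance) coverage steps of one intervention."""

    record: InterventionRecord
    row_index: int
    cost_curve: CostBenefitCurve
    benefit_curve: CostBenefitCurve
    steps: tuple[IncrementalAlternative, ...]

    @property
    def id(self) -> str:
        return self.record.id

    def steps_above(self, coverage: float) -> list[IncrementalAlternative]:
        return [s for s in self.steps if s.theta_from >= coverage - _EPS]

    def next_step(self, coverage: float) -> IncrementalAlternative | None:
        above = self.steps_above(coverage)
        return above[0] if above else None

    @property
    def total_cost(self) -> float:
        return sum(s.delta_cost for s in self.steps)

    @property
    def total_benefit(self) -> float:
        return sum(s.delta_benefit for s in self.steps)


def build_ladders(
    records: Sequence[InterventionRecord], config: AnalysisConfig
) -> list[Ladder]:
    """Fit curves and discretize every intervention for the given scenario."""
    ladders: list[Ladder] = []
    for row_index, record in enumerate(records):
        cost_curve = fit_anchor_curve(
            record.anchor_cost, config.grid_floor, record.id, "cost"
        )
        benefit_curve = fit_anchor_curve(
            record.anchor_benefit, config.grid_floor, record.id, "benefit"
        )
        if config.scenario == "all_or_nothing":
            level = config.all_or_nothing_level
            # Only the do-nothing point and the provision level are known, so
            # cost and benefit run linearly through the origin.
            lin_cost = CostBenefitCurve(
                record.id, "cost", "linear",
                a=0.0, b1=cost_curve.value(level) / level, b2=0.0, grid_floor=level,
            )
            lin_ben = CostBenefitCurve(
                record.id, "benefit", "linear",
                a=0.0, b1=benefit_curve.value(level) / level, b2=0.0, grid_floor=level,
            )
            pop = record.incident_population
            step = IncrementalAlternative(
                intervention_id=record.id,
                row_index=row_index,
                theta_from=0.0,
                theta_to=level,
                delta_cost=lin_cost.value(level) * pop * config.conversion_factor,
                delta_benefit=lin_ben.value(level) * pop,
                delta_weighted_benefit=apply_equity_weights(
                    0.0, level, lin_ben, config.weights, pop
                ),
                use_weighted=False,
            )
            ladders.append(Ladder(record, row_index, lin_cost, lin_ben, (step,)))
        else:
            steps = build_grid_alternatives(
                record, cost_curve, benefit_curve, config, row_index
            )
            ladders.append(Ladder(record, row_index, cost_curve, benefit_curve, tuple(steps)))
    return ladders


# ---------------------------------------------------------------------------
# solution containers


@dataclass
class InterventionOutcome:
    """Funded coverage and health effects of one intervention."""

    intervention_id: str
    name: str
    row_index: int
    coverage: float = 0.0
    spend: float = 0.0
    dalys: float = 0.0
    weighted_dalys: float = 0.0
    last_icer: float | None = None


@dataclass
class Solution:
    """Result of one optimization run."""

    scenario: str
    budget: float
    conversion_factor: float
    outcomes: list[InterventionOutcome] = field(default_factory=list)
    iteration_log: list[dict] = field(default_factory=list)
    pre_fractional_underspend: float | None = None
    fractional_intervention_id: str | None = None
    fractional_coverage: float | None = None
    marginal_icer: float | None = None
    marginal_intervention_id: str | None = None
    league_exceptions: list[dict] = field(default_factory=list)

    @property
    def total_spend(self) -> float:
        return sum(o.spend for o in self.outcomes)

    @property
    def total_dalys(self) -> float:
        return sum(o.dalys for o in self.outcomes)

    @property
    def total_weighted_dalys(self) -> float:
        return sum(o.weighted_dalys for o in self.outcomes)

    @property
    def underspend(self) -> float:
        return self.budget - self.total_spend

    @property
    def n_covered(self) -> int:
        return sum(1 for o in self.outcomes if o.coverage > _EPS)

    def coverage_vector(self) -> dict[str, float]:
        return {o.intervention_id: o.coverage for o in self.outcomes}

    def outcome(self, intervention_id: str) -> InterventionOutcome:
        for o in self.outcomes:
            if o.intervention_id == intervention_id:
                return o
        raise KeyError(intervention_id)

    def to_json_obj(self) -> dict:
        return {
            "scenario": self.scenario,
            "budget": self.budget,
            "conversion_factor": self.conversion_factor,
            "totals": {
                "spend": self.total_spend,
                "dalys": self.total_dalys,
                "weighted_dalys": self.total_weighted_dalys,
                "underspend": self.underspend,
            },
            "pre_fractional_underspend": self.pre_fractional_underspend,
            "marginal_icer": self.marginal_icer,
            "marginal_intervention_id": self.marginal_intervention_id,
            "fractional_intervention_id": self.fractional_intervention_id,
            "fractional_coverage": self.fractional_coverage,
            "league_exceptions": self.league_exceptions,
            "interventions": [
                {
                    "id": o.intervention_id,
                    "name": o.name,
                    "coverage": o.coverage,
                    "spend": o.spend,
                    "dalys": o.dalys,
                    "weighted_dalys": o.weighted_dalys,
                    "icer_at_coverage": o.last_icer,
                }
                for o in self.outcomes
            ],
            "iteration_log": self.iteration_log,
        }


def _empty_solution(
    ladders: Sequence[Ladder], scenario: str, budget: float, conversion_factor: float
) -> Solution:
    return Solution(
        scenario=scenario,
        budget=budget,
        conversion_factor=conversion_factor,
        outcomes=[
            InterventionOutcome(L.id, L.record.name, L.row_index) for L in ladders
        ],
    )


# ---------------------------------------------------------------------------
# step 2: rank and fill


def _rank_and_fill(
    solution: Solution,
    alternatives: Sequence[IncrementalAlternative],
    budget: float,
    pass_no: int,
) -> int:
    """Admit alternatives in ascending ICER order; stop at the first that
    does not fit in the remaining budget.  Returns the number admitted."""
    tol = _EPS * max(budget, 1.0)
    order = sorted(
        (a for a in alternatives if a.admissible),
        key=lambda a: (a.icer, a.row_index, a.theta_from),
    )
    admitted = 0
    for alt in order:
        remaining = budget - solution.total_spend
        if alt.delta_cost > remaining + tol:
            solution.iteration_log.append(
                {
                    "pass": pass_no,
                    "action": "stop",
                    "intervention": alt.intervention_id,
                    "theta_from": alt.theta_from,
                    "theta_to": alt.theta_to,
                    "icer": alt.icer,
                    "delta_cost": alt.delta_cost,
                    "remaining": remaining,
                }
            )
            break
        out = solution.outcome(alt.intervention_id)
        if abs(alt.theta_from - out.coverage) > 1e-9:
            raise OptimizerError(
                f"{alt.intervention_id}: non-contiguous admission "
                f"({alt.theta_from} after coverage {out.coverage})"
            )
        out.coverage = alt.theta_to
        out.spend += alt.delta_cost
        out.dalys += alt.delta_benefit
        out.weighted_dalys += alt.delta_weighted_benefit
        out.last_icer = alt.icer
        admitted += 1
        solution.iteration_log.append(
            {
                "pass": pass_no,
                "action": "admit",
                "intervention": alt.intervention_id,
                "theta_from": alt.theta_from,
                "theta_to": alt.theta_to,
                "icer": alt.icer,
                "delta_cost": alt.delta_cost,
                "introduced_in_loop": pass_no > 0 and alt.theta_from == 0.0,
            }
        )
    return admitted


def greedy_fill(
    ladders: Sequence[Ladder],
    budget: float,
    scenario: str = "variable_coverage",
    conversion_factor: float = 1.0,
) -> Solution:
    """Steps 1 and 2: dominance elimination then rank-and-fill.

    Returns a partial solution (no underspend reallocation yet).
    """
    solution = _empty_solution(ladders, scenario, budget, conversion_factor)
    alts = [a for L in ladders for a in eliminate_dominated(list(L.steps))]
    _rank_and_fill(solution, alts, budget, pass_no=0)
    return solution


# ---------------------------------------------------------------------------
# step 3: underspend reallocation


def _affordable_prefix(
    steps: Sequence[IncrementalAlternative], underspend: float, tol: float
) -> list[IncrementalAlternative]:
    """Leading steps whose cumulative additional cost fits the underspend.

    Coverage must stay contiguous, so an alternative is affordable only if
    everything between the current coverage and its upper end is: the
    affordability filter keeps the maximal prefix by cumulative cost.
    """
    prefix: list[IncrementalAlternative] = []
    cum = 0.0
    for s in steps:
        cum += s.delta_cost
        if cum > underspend + tol:
            break
        prefix.append(s)
    return prefix


def underspend_loop(
    partial: Solution,
    ladders: Sequence[Ladder],
    budget: float,
    max_passes: int = 1000,
) -> Solution:
    """Reallocate the budget underspend, then fractionally fund the margin.

    Each pass recomputes, for every intervention, the grid steps above its
    current coverage (previously dominated or skipped steps re-enter),
    eliminates those whose cumulative additional cost exceeds the underspend,
    re-applies dominance, re-ranks, and admits.  The loop exits on the first
    pass that admits nothing.  Finally the single next grid increment with
    the lowest ICER is funded fractionally, coverage and benefits advancing
    linearly in spend, which exhausts the budget whenever any increment with
    positive benefit remains.
    """
    solution = partial
    tol = _EPS * max(budget, 1.0)
    for pass_no in range(1, max_passes + 1):
        underspend = budget - solution.total_spend
        candidates: list[IncrementalAlternative] = []
        for ladder in ladders:
            coverage = solution.outcome(ladder.id).coverage
            steps = ladder.steps_above(coverage)
            prefix = _affordable_prefix(steps, underspend, tol)
            if prefix:
                candidates.extend(eliminate_dominated(prefix))
        if not candidates:
            break
        admitted = _rank_and_fill(solution, candidates, budget, pass_no)
        if admitted == 0:
            break
    else:  # pragma: no cover - termination guard
        raise OptimizerError(f"underspend loop did not terminate in {max_passes} passes")

    # terminal fractional scale-up of the single cheapest next increment
    underspend = budget - solution.total_spend
    solution.pre_fractional_underspend = underspend
    next_steps = []
    for ladder in ladders:
        step = ladder.next_step(solution.outcome(ladder.id).coverage)
        if step is not None and step.effective_benefit > 0.0:
            next_steps.append(step)
    if underspend > tol and next_steps:
        best = min(next_steps, key=lambda a: (a.icer, a.row_index))
        fraction = min(underspend / best.delta_cost, 1.0)
        out = solution.outcome(best.intervention_id)
        out.coverage = best.theta_from + fraction * (best.theta_to - best.theta_from)
        out.spend += underspend
        out.dalys += fraction * best.delta_benefit
        out.weighted_dalys += fraction * best.delta_weighted_benefit
        out.last_icer = best.icer
        solution.fractional_intervention_id = best.intervention_id
        solution.fractional_coverage = out.coverage
        solution.marginal_icer = best.icer
        solution.marginal_intervention_id = best.intervention_id
        solution.iteration_log.append(
            {
                "pass": "terminal",
                "action": "fractional",
                "intervention": best.intervention_id,
                "theta_from": best.theta_from,
                "theta_to": out.coverage,
                "icer": best.icer,
                "delta_cost": underspend,
            }
        )
    else:
        admissions = [e for e in solution.iteration_log if e["action"] == "admit"]
        if admissions:
            last = admissions[-1]
            solution.marginal_icer = last["icer"]
            solution.marginal_intervention_id = last["intervention"]

    if solution.marginal_icer is not None:
        for entry in solution.iteration_log:
            if entry["action"] == "admit" and entry["icer"] > solution.marginal_icer + _EPS:
                solution.league_exceptions.append(
                    {
                        "intervention": entry["intervention"],
                        "theta_from": entry["theta_from"],
                        "theta_to": entry["theta_to"],
                        "icer": entry["icer"],
                        "marginal_icer": solution.marginal_icer,
                    }
                )
    return solution


# ---------------------------------------------------------------------------
# scenarios


def solve_scenario(
    records: Sequence[InterventionRecord], config: AnalysisConfig
) -> Solution:
    """Run the full three-step procedure for the configured scenario."""
    ladders = build_ladders(records, config)
    partial = greedy_fill(
        ladders, config.budget, config.scenario, config.conversion_factor
    )
    return underspend_loop(partial, ladders, config.budget)


def marginal_productivity(solution: Solution) -> float:
    """ICER of the last (possibly fractional) increment funded.

    This is the cost per (effective) DALY at which the budget constraint
    binds - the empirical marginal productivity of the discretionary budget.
    Deviations from the league-table property (an admitted increment costing
    more per DALY than the margin, which the reallocation loop can produce)
    are reported in ``solution.league_exceptions``, not hidden.
    """
    if solution.marginal_icer is None:
        raise EmptySolutionError("no increment was funded; marginal ICER undefined")
    return solution.marginal_icer


# ---------------------------------------------------------------------------
# currency calibration


@dataclass(frozen=True)
class Landmark:
    """A structural condition a calibrated solution must reproduce."""

    scenario: str = "variable_coverage"
    fractional_intervention_id: str | None = "pneumonia_children"
    coverage_band: tuple[float, float] | None = (0.70, 0.75)
    all_covered: bool = False

    def check(self, solution: Solution, ladders: Sequence[Ladder]) -> bool:
        if self.all_covered:
            total = sum(L.total_cost for L in ladders)  # already in US$ at this factor
            return total <= solution.budget * (1.0 + _EPS)
        if solution.fractional_intervention_id != self.fractional_intervention_id:
            return False
        if self.coverage_band is not None:
            lo, hi = self.coverage_band
            cov = solution.fractional_coverage
            return cov is not None and lo + _EPS < cov < hi - _EPS
        return True


@dataclass(frozen=True)
class CalibrationResult:
    factor: float
    bracket: tuple[float, float]
    n_evaluations: int


def calibrate_conversion(
    records: Sequence[InterventionRecord],
    config: AnalysisConfig,
    landmark: Landmark | None = None,
    bracket: tuple[float, float] = (0.25, 25.0),
    coarse_points: int = 2500,
    tol: float = 1e-4,
) -> CalibrationResult:
    """Search the 2000 Int$ -> 2015 US$ factor reproducing a landmark.

    The factor is not stated with the source data, so it is treated as a free
    parameter: the predicate is evaluated on a coarse factor grid over
    ``bracket``, the edges of the satisfying interval are refined by
    bisection, and the midpoint of that interval is returned.  Deterministic
    given bracket and tolerance.
    """
    if landmark is None:
        landmark = Landmark()
    evaluations = 0

    def predicate(factor: float) -> bool:
        nonlocal evaluations
        evaluations += 1
        cfg = config.with_(conversion_factor=factor, scenario=landmark.scenario)
        ladders = build_ladders(records, cfg)
        partial = greedy_fill(ladders, cfg.budget, cfg.scenario, factor)
        sol = underspend_loop(partial, ladders, cfg.budget)
        return landmark.check(sol, ladders)

    lo, hi = bracket
    grid = np.linspace(lo, hi, coarse_points)
    flags = [predicate(f) for f in grid]
    true_idx = [i for i, ok in enumerate(flags) if ok]
    if not true_idx:
        def describe(factor: float) -> str:
            cfg = config.with_(conversion_factor=factor, scenario=landmark.scenario)
            ladders = build_ladders(records, cfg)
            sol = underspend_loop(
                greedy_fill(ladders, cfg.budget, cfg.scenario, factor),
                ladders,
                cfg.budget,
            )
            return (
                f"factor {factor:g}: terminal fractional intervention "
                f"{sol.fractional_intervention_id!r} at coverage "
                f"{sol.fractional_coverage}"
            )

        raise CalibrationError(
            "landmark unattainable on the bracket; "
            + describe(lo)
            + "; "
            + describe(hi)
        )

    # take the longest contiguous satisfying run
    runs: list[tuple[int, int]] = []
    start = true_idx[0]
    prev = true_idx[0]
    for i in true_idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])

    def refine(a: float, b: float) -> float:
        """Bisect the predicate's flip point between a and b."""
        fa = predicate(a)
        while b - a > tol:
            mid = 0.5 * (a + b)
            if predicate(mid) == fa:
                a = mid
            else:
                b = mid
        return 0.5 * (a + b)

    lo_edge = grid[i0] if i0 == 0 else refine(grid[i0 - 1], grid[i0])
    hi_edge = grid[i1] if i1 == len(grid) - 1 else refine(grid[i1], grid[i1 + 1])
    if hi_edge < lo_edge:  # pragma: no cover - defensive
        lo_edge, hi_edge = hi_edge, lo_edge
    return CalibrationResult(
        factor=0.5 * (lo_edge + hi_edge),
        bracket=(lo_edge, hi_edge),
        n_evaluations=evaluations,
    )
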