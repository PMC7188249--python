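"""Incremental coverage alternatives, equity weighting and dominance.

Each intervention's coverage choices are discretized into mutually exclusive
incremental steps: (0, 50%], then 5% steps up to 100% on the default grid.
Every step carries its incremental budget impact (2015 US$ after currency
conversion), incremental DALYs averted, equity-weighted DALYs, and the ICER
of the step.

Dominance elimination within an intervention removes steps that buy no
health at positive cost (strict dominance, treated as an infinite ICER) and
steps whose ICER exceeds that of the next step up (extended dominance).  An
eliminated step is merged into its successor - incremental costs and
benefits are summed and the ICER recomputed - so total cost and benefit over
the ladder are conserved exactly and the retained sequence has non-decreasing
ICERs in coverage order.  This is the lower convex envelope of the
intervention's cumulative (cost, benefit) staircase.

Equity weighting is applied on the 5% grid *before* any merging, so merged
intervals spanning a weight-band boundary are handled by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .curves import CostBenefitCurve, incremental
from .data_model import (
    COVERAGE_ANCHORS,
    AnalysisConfig,
    EquityWeightSchedule,
    InterventionRecord,
    UhcpackError,
)

__all__ = [
    "IncrementalAlternative",
    "build_grid_alternatives",
    "apply_equity_weights",
    "eliminate_dominated",
    "merge_alternatives",
]


class AlternativeError(UhcpackError):
    pass


@dataclass(frozen=True)
class IncrementalAlternative:
    """A (theta_from, theta_to] coverage step of one intervention.

    ``delta_cost`` is in 2015 US$ per year (population-scaled, after currency
    conversion); ``delta_benefit`` in DALYs averted per year;
    ``delta_weighted_benefit`` in equity-weighted DALYs per year.
    ``use_weighted`` selects which benefit the ICER is computed on (true in
    the equity-weighted scenario).  ``merged_from`` lists the constituent
    grid steps, in coverage order.
    """

    intervention_id: str
    row_index: int
    theta_from: float
    theta_to: float
    delta_cost: float
    delta_benefit: float
    delta_weighted_benefit: float
    use_weighted: bool = False
    merged_from: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.theta_from >= self.theta_to:
            raise AlternativeError(
                f"{self.intervention_id}: empty step ({self.theta_from}, {self.theta_to}]"
            )
        if not self.merged_from:
            object.__setattr__(
                self, "merged_from", ((self.theta_from, self.theta_to),)
            )

    @property
    def effective_benefit(self) -> float:
        """The benefit the ICER is computed on (weighted when configured)."""
        return self.delta_weighted_benefit if self.use_weighted else self.delta_benefit

    @property
    def icer(self) -> float:
        """Incremental cost per (effective) DALY averted.

        Steps with no effective health gain at positive cost are 'never
        cost-effective': their ICER is +inf and they are excluded from
        ranking.
        """
        if self.effective_benefit > 0.0:
            return self.delta_cost / self.effective_benefit
        return math.inf

    @property
    def admissible(self) -> bool:
        return math.isfinite(self.icer)


def apply_equity_weights(
    theta_from: float,
    theta_to: float,
    benefit_curve: CostBenefitCurve,
    weights: EquityWeightSchedule,
    incident_population: float,
) -> float:
    """Equity-weighted incremental DALYs over (theta_from, theta_to].

    The interval is partitioned at every weight-band boundary and each
    sub-interval's incremental benefit is multiplied by the weight of the
    band it falls in.
    """
    if not (0.0 <= theta_from < theta_to <= 1.0 + 1e-12):
        raise AlternativeError(f"invalid interval ({theta_from}, {theta_to}]")
    cuts = [theta_from]
    for b in weights.boundaries():
        if theta_from < b < theta_to:
            cuts.append(b)
    cuts.append(theta_to)
    total = 0.0
    for lo, hi in zip(cuts, cuts[1:]):
        w = weights.weight_at(0.5 * (lo + hi))
        total += w * incremental(benefit_curve, lo, hi, incident_population)
    return total


def build_grid_alternatives(
    record: InterventionRecord,
    cost_curve: CostBenefitCurve,
    benefit_curve: CostBenefitCurve,
    config: AnalysisConfig,
    row_index: int = 0,
) -> list[IncrementalAlternative]:
    """One alternative per grid step: (0, floor], then each 5% step to 1.0.

    Incremental costs and benefits are differences of the cumulative curves
    (so they telescope exactly); costs are converted to 2015 US$.  Increments
    extrapolated beyond the highest anchor (95%) that come out negative are
    clamped to zero with a warning; negative increments *between* anchors are
    flagged and left to dominance elimination, which absorbs them.
    """
    pop = record.incident_population
    top_anchor = max(COVERAGE_ANCHORS)
    use_weighted = config.scenario == "equity_weighted"
    alts: list[IncrementalAlternative] = []
    grid = config.grid
    for lo, hi in zip(grid, grid[1:]):
        d_cost = incremental(cost_curve, lo, hi, pop) * config.conversion_factor
        d_ben = incremental(benefit_curve, lo, hi, pop)
        d_wben = apply_equity_weights(lo, hi, benefit_curve, config.weights, pop)
        if lo >= top_anchor - 1e-12:  # extrapolated step
            if d_cost < 0.0 or d_ben < 0.0:
                warnings.warn(
                    f"{record.id}: negative extrapolated increment on ({lo}, {hi}] "
                    "clamped to 0",
                    stacklevel=2,
                )
                d_cost = max(d_cost, 0.0)
                d_ben = max(d_ben, 0.0)
                d_wben = max(d_wben, 0.0)
        elif d_ben < 0.0 or d_cost < 0.0:
            warnings.warn(
                f"{record.id}: negative increment on interior grid step ({lo}, {hi}]; "
                "left to dominance elimination",
                stacklevel=2,
            )
        alts.append(
            IncrementalAlternative(
                intervention_id=record.id,
                row_index=row_index,
                theta_from=lo,
                theta_to=hi,
                delta_cost=d_cost,
                delta_benefit=d_ben,
                delta_weighted_benefit=d_wben,
                use_weighted=use_weighted,
            )
        )
    return alts


def merge_alternatives(
    first: IncrementalAlternative, second: IncrementalAlternative
) -> IncrementalAlternative:
    """Merge an eliminated step into its successor (deltas are summed)."""
    if first.intervention_id != second.intervention_id:
        raise AlternativeError("cannot merge steps of different interventions")
    if abs(first.theta_to - second.theta_from) > 1e-12:
        raise AlternativeError(
            f"{first.intervention_id}: steps ({first.theta_from}, {first.theta_to}] "
            f"and ({second.theta_from}, {second.theta_to}] are not adjacent"
        )
    return replace(
        first,
        theta_to=second.theta_to,
        delta_cost=first.delta_cost + second.delta_cost,
        delta_benefit=first.delta_benefit + second.delta_benefit,
        delta_weighted_benefit=first.delta_weighted_benefit
        + second.delta_weighted_benefit,
        merged_from=first.merged_from + second.merged_from,
    )


def eliminate_dominated(
    alts: Sequence[IncrementalAlternative],
) -> list[IncrementalAlternative]:
    """Strict and extended dominance elimination with forward merging.

    Given the coverage-ordered steps of a single intervention, repeatedly
    merges any step whose ICER exceeds the next step's ICER into that next
    step (zero- or negative-benefit steps carry an infinite ICER and are thus
    absorbed as strictly dominated), until the retained ICERs are
    non-decreasing.  Ties (equal ICERs) are retained separately, preserving
    the finer granularity.

    Total cost and benefit are conserved exactly.  Trailing steps with no
    effective benefit cannot be merged forward and are retained flagged
    inadmissible (infinite ICER) - an all-zero-benefit intervention collapses
    to a single never-cost-effective alternative.
    """
    if not alts:
        return []
    ids = {a.intervention_id for a in alts}
    if len(ids) != 1:
        raise AlternativeError(
            f"dominance elimination is within-intervention only; got {sorted(ids)}"
        )
    retained: list[IncrementalAlternative] = []
    for alt in alts:
        cur = alt
        # adjacent never-cost-effective steps (both +inf) collapse into one
        while retained and (
            retained[-1].icer > cur.icer
            or (math.isinf(retained[-1].icer) and math.isinf(cur.icer))
        ):
            cur = merge_alternatives(retained.pop(), cur)
        retained.append(cur)
    return retained
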