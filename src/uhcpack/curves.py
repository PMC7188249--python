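"""Cumulative cost and benefit as functions of coverage.

Three coverage anchors (50%, 80%, 95%) pin each intervention's cumulative
per-capita cost and benefit.  Where the three anchors are collinear the
relationship is taken to be linear; otherwise the unique quadratic through
them is used.  Below the lowest grid coverage (50% by default) incremental
costs and benefits are assumed constant, i.e. the curve runs linearly through
the origin up to its value at the grid floor, so that v(0) = 0 exactly.

Incremental quantities are always computed as differences of the cumulative
curve; this conserves totals exactly under any partition of a coverage
interval.  The analytic derivative is exposed purely as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_model import UhcpackError

__all__ = [
    "CostBenefitCurve",
    "CurveError",
    "fit_anchor_curve",
    "cumulative_total",
    "incremental",
    "marginal_rate",
]

#: Relative tolerance on the middle anchor's chord residual below which the
#: three anchors are treated as collinear.  Printed 3-decimal data are either
#: exactly collinear or clearly curved, so the precise value is not delicate.
LINEAR_TOLERANCE = 1e-6


class CurveError(UhcpackError):
    """Invalid anchors or coverage outside the curve's domain."""


@dataclass(frozen=True)
class CostBenefitCurve:
    """A fitted cumulative per-capita curve v(theta) on coverage theta.

    On [grid_floor, 1] the curve is the polynomial ``a + b1*theta +
    b2*theta**2``; on [0, grid_floor) it is the ray ``(theta/grid_floor) *
    v(grid_floor)`` through the origin.
    """

    intervention_id: str
    quantity: str  # "cost" or "benefit"
    form: str  # "linear" or "quadratic"
    a: float
    b1: float
    b2: float
    grid_floor: float

    @property
    def floor_value(self) -> float:
        return self._poly(self.grid_floor)

    def _poly(self, theta: float) -> float:
        return self.a + self.b1 * theta + self.b2 * theta * theta

    def value(self, theta: float) -> float:
        """Cumulative per-capita value at coverage ``theta`` in [0, 1]."""
        if not (0.0 <= theta <= 1.0 + 1e-12):
            raise CurveError(
                f"{self.intervention_id}/{self.quantity}: coverage {theta} outside [0, 1]"
            )
        theta = min(theta, 1.0)
        if theta < self.grid_floor:
            return (theta / self.grid_floor) * self.floor_value
        return self._poly(theta)

    __call__ = value

    def derivative(self, theta: float) -> float:
        """Marginal per-capita rate d v / d theta on [grid_floor, 1]."""
        if not (self.grid_floor <= theta <= 1.0 + 1e-12):
            raise CurveError(
                f"{self.intervention_id}/{self.quantity}: derivative requested at "
                f"{theta}, below the grid floor {self.grid_floor} the curve is the "
                f"origin ray with slope {self.origin_segment_rate:.6g}"
            )
        return self.b1 + 2.0 * self.b2 * min(theta, 1.0)

    @property
    def origin_segment_rate(self) -> float:
        """Constant incremental rate on [0, grid_floor)."""
        return self.floor_value / self.grid_floor

    def to_json_obj(self) -> dict:
        return {
            "intervention_id": self.intervention_id,
            "quantity": self.quantity,
            "form": self.form,
            "coefficients": [self.a, self.b1, self.b2],
            "grid_floor": self.grid_floor,
            "floor_value": self.floor_value,
        }


def fit_anchor_curve(
    anchors: Mapping[float, float],
    grid_floor: float = 0.50,
    intervention_id: str = "",
    quantity: str = "",
    linear_tol: float = LINEAR_TOLERANCE,
) -> CostBenefitCurve:
    """Fit the interpolating curve through three coverage anchors.

    If the middle anchor lies on the chord between the outer anchors (within
    ``linear_tol`` relative to the anchor scale), the least-squares line
    through the three points is used (it interpolates exactly in that case);
    otherwise the unique quadratic through the three points is solved
    exactly.
    """
    thetas = sorted(anchors)
    if len(thetas) != 3 or len(set(thetas)) != 3:
        raise CurveError(
            f"{intervention_id}/{quantity}: exactly three distinct anchors required, "
            f"got {sorted(anchors)}"
        )
    if any(not (0.0 < t <= 1.0) for t in thetas):
        raise CurveError(f"{intervention_id}/{quantity}: anchors outside (0, 1]")
    values = [float(anchors[t]) for t in thetas]
    if not (values[0] <= values[1] + 1e-15 and values[1] <= values[2] + 1e-15):
        raise CurveError(
            f"{intervention_id}/{quantity}: anchor values must be non-decreasing "
            f"in coverage, got {values}"
        )

    t0, t1, t2 = thetas
    v0, v1, v2 = values
    chord_mid = v0 + (v2 - v0) * (t1 - t0) / (t2 - t0)
    scale = max(abs(v0), abs(v1), abs(v2), 1e-30)
    if abs(v1 - chord_mid) <= linear_tol * scale:
        slope, intercept = np.polyfit(thetas, values, 1)
        a, b1, b2 = float(intercept), float(slope), 0.0
        form = "linear"
    else:
        vander = np.array([[1.0, t, t * t] for t in thetas])
        a, b1, b2 = (float(c) for c in np.linalg.solve(vander, np.array(values)))
        form = "quadratic"
    return CostBenefitCurve(
        intervention_id=intervention_id,
        quantity=quantity,
        form=form,
        a=a,
        b1=b1,
        b2=b2,
        grid_floor=grid_floor,
    )


def cumulative_total(curve: CostBenefitCurve, theta: float, incident_population: float) -> float:
    """Total annual value at coverage ``theta``: v(theta) x population."""
    return curve.value(theta) * incident_population


def incremental(
    curve: CostBenefitCurve,
    theta_from: float,
    theta_to: float,
    incident_population: float,
) -> float:
    """Incremental annual value over (theta_from, theta_to].

    Computed as the difference of cumulative totals, so it is additive over
    adjacent sub-intervals to machine precision.
    """
    if theta_from >= theta_to:
        raise CurveError(
            f"{curve.intervention_id}/{curve.quantity}: empty coverage interval "
            f"({theta_from}, {theta_to}]"
        )
    return cumulative_total(curve, theta_to, incident_population) - cumulative_total(
        curve, theta_from, incident_population
    )


def marginal_rate(curve: CostBenefitCurve, theta: float) -> float:
    """Per-capita derivative of the fitted polynomial (diagnostic only)."""
    return curve.derivative(theta)


def check_grid_monotone(curve: CostBenefitCurve, grid: tuple[float, ...]) -> list[tuple[float, float]]:
    """Return grid steps on which the fitted curve decreases, with a warning.

    Anchors are non-decreasing by validation, but a fitted quadratic can dip
    between or beyond them when the printed inputs are coarsely rounded.
    Such steps are flagged here and later absorbed by dominance elimination
    rather than silently accepted.
    """
    bad: list[tuple[float, float]] = []
    for lo, hi in zip(grid, grid[1:]):
        if curve.value(hi) < curve.value(lo) - 1e-15:
            bad.append((lo, hi))
    if bad:
        warnings.warn(
            f"{curve.intervention_id}/{curve.quantity}: fitted curve decreases on "
            f"grid step(s) {bad}",
            stacklevel=2,
        )
    return bad
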