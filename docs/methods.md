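# Methods

## Model

Each intervention *i* has an incident population `P_i` (patients per year)
and cumulative per-patient annual cost `x_i(θ)` (2000 Int$) and benefit
`b_i(θ)` (DALYs averted) at coverage `θ` — the fraction of `P_i` reached.
The decision variable is one coverage level per intervention on the grid
`{0, 0.50, 0.55, …, 1.00}`; coverage is contiguous (whoever is cheapest to
reach is reached first; no gaps), so an intervention's alternatives enter
in coverage order and are mutually exclusive. The objective is total
(optionally equity-weighted) DALYs averted subject to
`Σ_i conversion_factor · x_i(θ_i) · P_i ≤ X` with `X` the discretionary
budget in 2015 US$.

"Per patient" means per member of the *incident* population. The source
table's column heading is ambiguous on this point; this reading is the only
one under which per-intervention health effects reach the package scale
(e.g. TB DOTS: 0.130 DALYs/case × 112,918 cases ≈ 14,700 DALYs at 95%
coverage), and it is pinned by a test.

### Curves

Three anchors (50/80/95%) determine each curve. If the middle anchor lies
on the chord of the outer two within a relative tolerance of `1e-6`
(3-decimal data are either exactly collinear or clearly curved; the value
is configurable and not delicate), the least-squares line is used —
which interpolates exactly in the collinear case; otherwise the unique
interpolating quadratic is solved exactly from the 3×3 Vandermonde system.
Below 50% coverage incremental costs and benefits are constant: the curve
is the ray through the origin to its 50% value, so `v(0) = 0` exactly.

All incremental quantities are *differences of the cumulative curve*, never
derivative × step: this makes increments additive over any partition to
machine precision and conserves totals exactly through dominance merging.
The analytic derivative `b1 + 2·b2·θ` is exposed as a diagnostic only.

Extrapolation 95→100% uses the fitted polynomial. With coarsely rounded
anchors a fitted quadratic can *decrease* on a grid step (it happens for
four benefit curves of the shipped table); decreasing extrapolated steps
are clamped to zero with a warning, decreasing interior steps are flagged
and left to dominance elimination, which absorbs them into their successor.

### Equity weights

A weight schedule maps coverage bands to multipliers ≥ 1 (default: ×2 on
(0.8, 0.9], ×4 on (0.9, 1.0], encoding the assumption that the people
reached last are the most disadvantaged). Weighting is applied on the 5%
grid *before* any merging, by partitioning an interval at every band
boundary; merged or all-or-nothing intervals spanning a boundary are
therefore handled by construction. In the all-or-nothing scenario benefits
are linear on (0, 0.95], so the weighted/unweighted ratio of a full step is
(0.8 + 2·0.1 + 4·0.05)/0.95 ≈ 1.263, and a fractional step preserves that
ratio because fractional benefits advance linearly in spend.

### Dominance elimination

Within an intervention, a step with no effective health gain at positive
cost carries an infinite ICER (strictly dominated, "never cost-effective");
a step whose ICER exceeds the next step's is extended-dominated. Eliminated
steps are merged into their successor (deltas summed, ICER recomputed)
until the retained ICER sequence is non-decreasing — a stack pass that
computes the lower convex envelope of the cumulative (cost, benefit)
staircase. Ties are kept separate to preserve granularity. Adjacent
infinite-ICER steps merge with each other, so an all-zero-benefit
intervention collapses to a single flagged, unrankable alternative.

### Optimization

*Fill*: non-dominated alternatives across interventions are sorted by
(ICER, input row order, coverage) and admitted until the first whose cost
exceeds the remaining budget.

*Reallocation loop*: with underspend `u = X − spend`, every grid step above
an intervention's current coverage whose *cumulative* additional cost
exceeds `u` is eliminated (cumulative, because coverage must stay
contiguous: a step is only reachable through everything below it);
dominance is re-applied to the survivors (previously dominated or skipped
steps re-enter, recomputed incremental to current coverage), and the fill
repeats. The loop exits on the first pass that admits nothing; a guard caps
passes and a pass that admits nothing cannot loop.

*Terminal fraction*: among each intervention's single next grid increment
(never a merged alternative) with positive effective benefit, the lowest
ICER is funded fractionally, coverage and benefit advancing linearly in
spend, which exhausts the budget. Its ICER is reported as the marginal
productivity of the budget; admitted increments costing more per DALY than
the margin (possible through the loop) are listed in
`solution.league_exceptions`, not hidden.

### Known limitations of the procedure

The procedure is a heuristic, and two of its failure modes are measurable
with the enumeration oracles in `validation`:

- When the reallocation loop *does* admit steps after the initial fill
  stops, the budget is spent at worse rates than the stopped alternative's;
  on about one synthetic instance in seven this lands the heuristic below
  even the best pure grid package (a large 0→50% entry block gets crowded
  out by cheaper, less cost-effective steps). Consequently total health is
  not always monotone in the budget on synthetic instances. On the shipped
  data, a 20-point budget sweep is monotone in every scenario.
- When the loop admits nothing ("clean" runs, about 30% of synthetic
  instances, and how the shipped analysis behaves near its landmark), fill
  plus one fractional step is provably optimal for the relaxation that
  allows a single divisible step, and the oracle comparison confirms exact
  agreement on every such instance.

The validation suite reports the first class as *diagnostics* (properties
of the method) and any violation in the second class as *failures*
(implementation bugs).

## Currency calibration

The 2000 Int$ → 2015 US$ factor is not part of the source data and is never
silently defaulted for the shipped analysis. `calibrate_conversion` scans a
factor bracket (default [0.25, 25], 2500 points — the satisfying windows
are a few hundredths wide because the package structure reshuffles as the
factor moves) for the region where a structural landmark holds, refines the
edges by bisection and returns the midpoint. The default landmark: the
scenario-1 budget is exhausted while fractionally scaling pneumonia
treatment (children) inside the 70–75% band. On the shipped table this
gives ≈ 4.2968 (window ≈ [4.283, 4.311]).

## Synthetic data

`SyntheticSpec` samples per-patient curves directly — base value at 50%
coverage, slope, curvature, with monotonicity on [0.5, 1] enforced by
construction — and evaluates them at the anchors, so three-point fitting
recovers the sampled curve exactly. Defaults mirror the shipped table:
convex costs (curvature 0–1.5× the base value), weakly concave benefits
(−0.4–0×), populations 2×10⁴–5×10⁶, per-patient 50% costs 0.03–1.0 Int$,
suite budgets 30–70% of the full-coverage cost. Optional multiplicative
anchor noise is re-monotonized by a running maximum. What the generator
does *not* emulate: correlation between cost and benefit levels, the
extreme cost outlier (severe malnutrition), zero-benefit rows, and
3-decimal rounding — so synthetic results say nothing about rounding
sensitivity (see below). Oracle checks enumerate up to 6 interventions × 12
levels; suites use 4 × 12 (≈20k vectors, vectorized).

## Sensitivity to the printed precision of the shipped table

The shipped anchors are printed to 3 decimals, and several benefit columns
are small (0.001–0.020 DALYs per patient), so their *increments* carry up
to ±50% relative rounding error, and rounding can even invert curvature
(a benefit of 0.005/0.007/0.009 is exactly convex at printed precision).
Aggregate results are robust: scenario totals move by only a few percent
because they are dominated by the large-benefit rows. Structural and
dollar-denominated margins are not: which intervention is marginal, the
ICER at the margin, the pre-fraction underspend, and per-intervention
retained dominance sets can all flip with third-decimal perturbations.
Two concrete consequences on the shipped table: IPTP prints 0.000 benefit
at every anchor and is therefore never funded although its unrounded
benefit is positive; and the serious-newborn-infections benefit column
(0.003/0.004/0.005) is convex at printed precision, so under equity weights
its early 5% steps are extended-dominated and the retained set is
{0→50%, 50→100%} rather than the finer set an unrounded table yields.
Analyses needing margin-level conclusions should supply unrounded inputs.

## Defaults

| parameter | default | units | why |
| --- | --- | --- | --- |
| budget | 15,000,000 | 2015 US$/yr | study condition (≈15% of domestic government health spending for the region) |
| conversion_factor | 1.0 | US$/Int$ | user decision; calibrated, never silently used for the shipped analysis |
| grid_floor / grid_step | 0.50 / 0.05 | coverage | anchors start at 50%; 5% steps are the published alternatives |
| weights | ×2 on (0.8,0.9], ×4 on (0.9,1.0] | — | illustrative equity stance on the two hardest-to-reach deciles; any schedule with weights ≥ 1 is accepted |
| all_or_nothing_level | 0.95 | coverage | the highest documented anchor |
| linear_tol | 1e-6 | relative | separates exactly-collinear printed anchors from curved ones |

Coverage is a fraction in [0, 1] everywhere in the API; percent formatting
exists only in the report layer.
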