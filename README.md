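# uhcpack

Optimal breadth-versus-depth design of a universal health coverage (UHC)
benefit package under a fixed budget.

## The problem

A ministry of health has a fixed discretionary budget `X` and a menu of `N`
candidate interventions. For each intervention *i* it knows, at coverage
anchors of 50%, 80% and 95% of the incident population, the cumulative
annual per-patient cost `x_i(θ)` (2000 international dollars) and the
cumulative annual per-patient health benefit `b_i(θ)` (DALYs averted), where
`θ` is the fraction of the incident population reached. Reaching the last
patients is the most expensive, so `x_i` is typically convex in `θ` while
`b_i` is flat or concave. The design problem is

```
max_θ  Σ_i  B_i(θ_i)      s.t.  Σ_i X_i(θ_i) ≤ X,   θ_i ∈ {0} ∪ [0.5, 1]
```

where `B_i`, `X_i` are population totals, optionally with equity weights
`w ≥ 1` multiplying benefits that accrue in the hardest-to-reach coverage
deciles (default: ×2 on (80%, 90%], ×4 on (90%, 100%]). At an interior
optimum the ratio of marginal (weighted) benefit to marginal cost is
equalized across interventions at the shadow price `λ` of the budget: the
ICER of the last funded increment measures the marginal productivity of the
budget in US$ per DALY averted.

`uhcpack` implements the operational version of this programme:

1. **Curves** — through each intervention's three anchors it fits a line if
   they are collinear, otherwise the exact interpolating quadratic;
   incremental costs and benefits below 50% coverage are constant (the curve
   runs through the origin).
2. **Alternatives** — coverage is discretized into mutually exclusive steps
   (0→50%, then 5% steps to 100%), each carrying its incremental cost,
   (equity-weighted) DALYs and ICER.
3. **Dominance** — within each intervention, steps that buy no health at
   positive cost (strict dominance) or cost more per DALY than the next
   step up (extended dominance) are merged forward until ICERs are
   non-decreasing in coverage — the convex envelope of the intervention's
   cost-benefit staircase.
4. **Optimization** — non-dominated alternatives across all interventions
   are funded in ascending ICER order until the next one no longer fits; an
   underspend-reallocation loop then re-ranks the still-affordable steps
   (previously dominated ones included) and admits them; finally the single
   cheapest next 5% increment is funded fractionally, exhausting the budget.

Three scenarios are built in: `variable_coverage` (ICERs on unweighted
DALYs), `equity_weighted` (ICERs on decile-weighted DALYs), and
`all_or_nothing` (each intervention either at 95% coverage or excluded,
with cost and benefit linear through the origin).

The package ships a 16-intervention WHO-CHOICE table for the AFR-E region
(maternal/newborn care, malaria, TB, immunization and child-nutrition
interventions, with incident populations for a country of 25 million) as
its built-in data set, plus a synthetic-instance generator and brute-force
enumeration oracles for validation.

## Worked example

The costs are in 2000 Int$ but the budget in 2015 US$; the conversion
factor is an explicit user decision. `calibrate_conversion` searches for
the factor at which a structural landmark of the analysis holds (by
default: the scenario-1 budget runs out while scaling pneumonia treatment
(children) through the 70–75% band), here ≈ 4.2968.

```python
import uhcpack as u

records = u.builtin_fixture()
config  = u.AnalysisConfig(budget=15e6)          # 2015 US$
config  = config.with_(conversion_factor=u.calibrate_conversion(records, config).factor)
solution = u.solve_scenario(records, config)
print(f"{solution.total_dalys:,.0f} DALYs averted, "
      f"marginal ICER {u.marginal_productivity(solution):,.0f} US$/DALY")
```

prints

```
198,477 DALYs averted, marginal ICER 482 US$/DALY
```

i.e. the optimal variable-coverage package averts about 198,000 DALYs per
year: 14 of the 16 interventions are funded (severe-malnutrition management
and IPTP avert no DALYs at the table's printed precision and are never
cost-effective), 8 at full coverage — malaria case management, TB DOTS,
bed nets, tetanus toxoid and skilled delivery among them — while pneumonia
treatment is the marginal intervention, scaled to ≈70% when the budget is
exhausted at 482 US$ per DALY. The same run from the shell, with per-
intervention league tables written to `out/`:

```bash
uhcpack solve --data builtin --scenario all --calibrate --out out
uhcpack validate --seeds 30        # synthetic property suite vs. the oracles
```

Forcing the conventional all-or-nothing package design
(`--scenario 3`) averts ≈190,800 DALYs — the measurable opportunity cost of
insisting on (near-)full coverage is about 7,700 DALYs per year, and under
equity weighting the trade-off between total health and reaching the last
deciles can be quantified the same way.

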