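"""Grid alternatives, equity weighting and dominance elimination."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import uhcpack as u
from uhcpack.alternatives import IncrementalAlternative, merge_alternatives
from uhcpack.curves import fit_anchor_curve


def _alt(icer_cost, benefit=1.0, lo=0.0, hi=0.5, **over):
    base = dict(
        intervention_id="x",
        row_index=0,
        theta_from=lo,
        theta_to=hi,
        delta_cost=icer_cost,
        delta_benefit=benefit,
        delta_weighted_benefit=benefit,
    )
    base.update(over)
    return IncrementalAlternative(**base)


def _chain(costs_benefits):
    """Adjacent steps (0,.5], (.5,.55], ... with given (cost, benefit)."""
    grid = [0.0] + [
        round(0.5 + 0.05 * i, 9) for i in range(len(costs_benefits))
    ]
    return [
        _alt(c, b, lo, hi)
        for (c, b), lo, hi in zip(costs_benefits, grid, grid[1:])
    ]


class TestBuildGridAlternatives:
    def test_eleven_steps_on_default_grid(self, fixture_records, base_config):
        for rec in fixture_records[:4]:
            cost = fit_anchor_curve(rec.anchor_cost, intervention_id=rec.id)
            ben = fit_anchor_curve(rec.anchor_benefit, intervention_id=rec.id)
            alts = u.build_grid_alternatives(rec, cost, ben, base_config)
            assert len(alts) == 11
            assert alts[0].theta_from == 0.0 and alts[0].theta_to == 0.5
            assert alts[-1].theta_to == 1.0

    def test_deltas_telescope_to_cumulative_total(self, fixture_records, base_config):
        rec = next(r for r in fixture_records if r.id == "tb_dots")
        cost = fit_anchor_curve(rec.anchor_cost)
        ben = fit_anchor_curve(rec.anchor_benefit)
        alts = u.build_grid_alternatives(rec, cost, ben, base_config)
        total = sum(a.delta_benefit for a in alts)
        assert total == pytest.approx(
            u.cumulative_total(ben, 1.0, rec.incident_population), abs=1e-9
        )

    def test_linear_benefit_gives_equal_five_percent_steps(self, base_config):
        rec = u.InterventionRecord(
            id="lin", name="linear", incident_population=1000,
            population_definition="synthetic",
            anchor_cost={0.50: 1.0, 0.80: 1.6, 0.95: 1.9},
            anchor_benefit={0.50: 0.5, 0.80: 0.8, 0.95: 0.95},
        )
        cost = fit_anchor_curve(rec.anchor_cost)
        ben = fit_anchor_curve(rec.anchor_benefit)
        alts = u.build_grid_alternatives(rec, cost, ben, base_config)
        steps = [a.delta_benefit for a in alts[1:]]
        assert all(s == pytest.approx(steps[0], abs=1e-9) for s in steps)
        # with all-1 weights, weighted equals unweighted on every step
        flat_cfg = base_config.with_(weights=u.EquityWeightSchedule.flat())
        flat = u.build_grid_alternatives(rec, cost, ben, flat_cfg)
        for a in flat:
            assert a.delta_weighted_benefit == pytest.approx(a.delta_benefit, abs=1e-12)


class TestApplyEquityWeights:
    def test_flat_schedule_is_identity(self):
        ben = fit_anchor_curve({0.50: 0.5, 0.80: 0.8, 0.95: 0.95})
        flat = u.EquityWeightSchedule.flat()
        got = u.apply_equity_weights(0.3, 0.97, ben, flat, 100.0)
        assert got == pytest.approx(u.incremental(ben, 0.3, 0.97, 100.0), abs=1e-12)

    def test_linear_benefit_hand_integration(self):
        # v(theta) = theta, pop 100, interval (0.85, 0.95]:
        # 0.05*100*2 + 0.05*100*4 = 30
        ben = fit_anchor_curve({0.50: 0.5, 0.80: 0.8, 0.95: 0.95})
        got = u.apply_equity_weights(
            0.85, 0.95, ben, u.EquityWeightSchedule.default(), 100.0
        )
        assert got == pytest.approx(30.0, abs=1e-9)

    def test_interval_spanning_all_bands_splits_at_boundaries(self):
        ben = fit_anchor_curve({0.50: 0.5, 0.80: 0.8, 0.95: 0.95})
        got = u.apply_equity_weights(
            0.0, 1.0, ben, u.EquityWeightSchedule.default(), 1.0
        )
        # 0.8*1 + 0.1*2 + 0.1*4 on the unit-slope line
        assert got == pytest.approx(1.4, abs=1e-9)

    def test_tetanus_full_coverage_weighting_ratio(self, fixture_records):
        # the weighted/unweighted ratio at 100% coverage for a near-linear
        # benefit curve is about (0.8 + 2*0.1 + 4*0.1) = 1.4
        rec = next(r for r in fixture_records if r.id == "tetanus_toxoid")
        ben = fit_anchor_curve(rec.anchor_benefit)
        pop = rec.incident_population
        weighted = u.apply_equity_weights(
            0.0, 1.0, ben, u.EquityWeightSchedule.default(), pop
        )
        unweighted = u.cumulative_total(ben, 1.0, pop)
        assert weighted / unweighted == pytest.approx(1.4, rel=0.2)


class TestEliminateDominated:
    def test_single_alternative_unchanged(self):
        alts = [_alt(10.0, 1.0)]
        assert u.eliminate_dominated(alts) == alts

    def test_three_step_extended_dominance_merges_middle(self):
        # ICERs (10, 30, 20): the 30-step is merged into the 20-step,
        # giving (10, 25) when both carry equal benefit
        alts = _chain([(10.0, 1.0), (30.0, 1.0), (20.0, 1.0)])
        kept = u.eliminate_dominated(alts)
        assert [round(a.icer, 6) for a in kept] == [10.0, 25.0]
        assert [
            (round(lo, 3), round(hi, 3)) for lo, hi in kept[1].merged_from
        ] == [(0.5, 0.55), (0.55, 0.6)]

    def test_zero_benefit_step_absorbed_as_strictly_dominated(self):
        alts = _chain([(5.0, 0.0), (5.0, 1.0)])
        kept = u.eliminate_dominated(alts)
        assert len(kept) == 1
        assert kept[0].icer == pytest.approx(10.0)

    def test_all_zero_benefit_collapses_to_one_flagged_alternative(self):
        alts = _chain([(5.0, 0.0), (3.0, 0.0), (2.0, 0.0)])
        kept = u.eliminate_dominated(alts)
        assert len(kept) == 1
        assert math.isinf(kept[0].icer)
        assert not kept[0].admissible
        assert kept[0].theta_from == 0.0 and kept[0].theta_to == 0.6

    def test_equal_icers_kept_separate(self):
        alts = _chain([(10.0, 1.0), (10.0, 1.0)])
        assert len(u.eliminate_dominated(alts)) == 2

    def test_mixed_intervention_input_rejected(self):
        a = _alt(1.0, 1.0)
        b = _alt(1.0, 1.0, lo=0.5, hi=0.55, intervention_id="y")
        with pytest.raises(u.UhcpackError):
            u.eliminate_dominated([a, b])

    def test_merge_requires_adjacency(self):
        a = _alt(1.0, 1.0, lo=0.0, hi=0.5)
        b = _alt(1.0, 1.0, lo=0.55, hi=0.6)
        with pytest.raises(u.UhcpackError):
            merge_alternatives(a, b)


@settings(deadline=None, max_examples=80)
@given(
    st.lists(
        st.tuples(st.floats(0.0, 50.0), st.floats(0.0, 5.0)),
        min_size=1,
        max_size=11,
    )
)
def test_dominance_conserves_totals_and_sorts_icers(costs_benefits):
    """Conservation through elimination and the non-decreasing stopping rule."""
    alts = _chain(costs_benefits)
    kept = u.eliminate_dominated(alts)
    assert sum(a.delta_cost for a in kept) == pytest.approx(
        sum(a.delta_cost for a in alts), abs=1e-9
    )
    assert sum(a.delta_benefit for a in kept) == pytest.approx(
        sum(a.delta_benefit for a in alts), abs=1e-9
    )
    icers = [a.icer for a in kept]
    finite = [i for i in icers if math.isfinite(i)]
    assert finite == sorted(finite)
    # infinite-ICER alternatives can only trail the finite ones
    assert icers == finite + [i for i in icers if math.isinf(i)]
    # coverage stays contiguous
    assert kept[0].theta_from == alts[0].theta_from
    assert kept[-1].theta_to == alts[-1].theta_to
    for a, b in zip(kept, kept[1:]):
        assert a.theta_to == pytest.approx(b.theta_from)


def test_raising_a_band_weight_never_raises_retained_weighted_icers():
    """Weight monotonicity: a larger equity weight cannot make any retained
    weighted ICER worse."""
    ben = fit_anchor_curve({0.50: 0.04, 0.80: 0.07, 0.95: 0.08})
    cost = fit_anchor_curve({0.50: 0.4, 0.80: 0.9, 0.95: 1.4})
    rec = u.InterventionRecord(
        id="w", name="w", incident_population=10_000,
        population_definition="synthetic",
        anchor_cost={0.50: 0.4, 0.80: 0.9, 0.95: 1.4},
        anchor_benefit={0.50: 0.04, 0.80: 0.07, 0.95: 0.08},
    )
    base = u.AnalysisConfig(scenario="equity_weighted")
    heavier = base.with_(
        weights=u.EquityWeightSchedule(bands=((0.8, 0.9, 2.0), (0.9, 1.0, 8.0)))
    )
    kept_base = u.eliminate_dominated(
        u.build_grid_alternatives(rec, cost, ben, base)
    )
    kept_heavy = u.eliminate_dominated(
        u.build_grid_alternatives(rec, cost, ben, heavier)
    )
    worst_base = max(a.icer for a in kept_base if a.admissible)
    worst_heavy = max(a.icer for a in kept_heavy if a.admissible)
    assert worst_heavy <= worst_base + 1e-9
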