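"""League-table fill, underspend reallocation, scenarios, calibration."""

import pytest

import uhcpack as u
from uhcpack.optimizer import (
    EmptySolutionError,
    Landmark,
    build_ladders,
    greedy_fill,
    underspend_loop,
)


def _record(id, pop, cost, ben, name=None):
    return u.InterventionRecord(
        id=id, name=name or id, incident_population=pop,
        population_definition="synthetic",
        anchor_cost=dict(zip((0.50, 0.80, 0.95), cost)),
        anchor_benefit=dict(zip((0.50, 0.80, 0.95), ben)),
    )


@pytest.fixture
def two_linear_records():
    # per-capita linear curves; population 1000 each
    cheap = _record("cheap", 1000, (1.0, 1.6, 1.9), (0.50, 0.80, 0.95))
    dear = _record("dear", 1000, (5.0, 8.0, 9.5), (0.50, 0.80, 0.95))
    return [cheap, dear]


class TestGreedyFill:
    def test_zero_budget_covers_nothing(self, two_linear_records):
        cfg = u.AnalysisConfig(budget=0.0)
        sol = u.solve_scenario(two_linear_records, cfg)
        assert sol.n_covered == 0
        assert sol.total_spend == 0.0
        assert sol.underspend == 0.0

    def test_slack_budget_funds_everything_fully(self, two_linear_records):
        cfg = u.AnalysisConfig(budget=1e9)
        sol = u.solve_scenario(two_linear_records, cfg)
        assert all(o.coverage == pytest.approx(1.0) for o in sol.outcomes)
        total_cost = (2.0 + 10.0) * 1000  # v(1) * population, factor 1
        assert sol.total_spend == pytest.approx(total_cost)
        assert sol.underspend == pytest.approx(1e9 - total_cost)

    def test_admission_follows_ascending_icer(self, two_linear_records):
        cfg = u.AnalysisConfig(budget=2_000.0)  # exactly the cheap one at 100%
        sol = u.solve_scenario(two_linear_records, cfg)
        assert sol.outcome("cheap").coverage == pytest.approx(1.0)
        # remaining budget is zero: the dear intervention stays out
        assert sol.outcome("dear").coverage == 0.0

    def test_stop_rule_halts_at_first_unaffordable(self, two_linear_records):
        ladders = build_ladders(two_linear_records, u.AnalysisConfig(budget=1.0))
        partial = greedy_fill(ladders, budget=2_500.0)
        # cheap fits fully (2000); dear's entry block (5000) does not: stop
        assert partial.outcome("cheap").coverage == pytest.approx(1.0)
        assert partial.outcome("dear").coverage == 0.0
        stops = [e for e in partial.iteration_log if e["action"] == "stop"]
        assert stops and stops[0]["intervention"] == "dear"


class TestUnderspendLoop:
    def test_second_pass_admits_stranded_cheap_alternative(self):
        # B (ICER 8/DALY on every step) fills first; its 55% step (400) does
        # not fit in the 150 left, so the fill stops with A (ICER 20, entry
        # block 100) skipped entirely.  The reallocation loop then admits A's
        # entry block and its 5% steps (10 each) with the stranded budget.
        a = _record("a", 100, (1.0, 1.6, 1.9), (0.050, 0.080, 0.095))
        b = _record("b", 1000, (4.0, 6.4, 7.6), (0.50, 0.80, 0.95))
        records = [a, b]
        cfg = u.AnalysisConfig(budget=4_150.0)
        ladders = build_ladders(records, cfg)
        partial = greedy_fill(ladders, cfg.budget)
        assert partial.outcome("b").coverage == pytest.approx(0.5)
        assert partial.outcome("a").coverage == 0.0
        sol = underspend_loop(partial, ladders, cfg.budget)
        assert sol.outcome("a").coverage == pytest.approx(0.75)
        assert sol.total_spend == pytest.approx(cfg.budget)
        introduced = [
            e for e in sol.iteration_log
            if e["action"] == "admit" and e.get("introduced_in_loop")
        ]
        assert introduced and introduced[0]["intervention"] == "a"

    def test_terminal_fraction_exhausts_budget_linearly_in_spend(
        self, two_linear_records
    ):
        cfg = u.AnalysisConfig(budget=2_700.0)
        sol = u.solve_scenario(two_linear_records, cfg)
        # cheap at 100% (2000), dear gets 700 of its 5000 entry block
        assert sol.fractional_intervention_id == "dear"
        assert sol.fractional_coverage == pytest.approx(0.5 * 700 / 5000)
        assert sol.outcome("dear").dalys == pytest.approx(500 * 700 / 5000)
        assert sol.total_spend == pytest.approx(cfg.budget)
        assert sol.pre_fractional_underspend == pytest.approx(700.0)

    def test_no_positive_benefit_increment_leaves_underspend(self):
        rec = _record("z", 1000, (1.0, 1.6, 1.9), (0.0, 0.0, 0.0))
        cfg = u.AnalysisConfig(budget=500.0)
        sol = u.solve_scenario([rec], cfg)
        assert sol.n_covered == 0
        assert sol.underspend == pytest.approx(500.0)
        with pytest.raises(EmptySolutionError):
            u.marginal_productivity(sol)


class TestSolutionInvariants:
    def test_budget_feasibility_and_single_fraction(self, fixture_records):
        cfg = u.AnalysisConfig(conversion_factor=4.3)
        for scenario in ("variable_coverage", "equity_weighted", "all_or_nothing"):
            sol = u.solve_scenario(fixture_records, cfg.with_(scenario=scenario))
            assert sol.total_spend <= cfg.budget * (1 + 1e-6)
            grid = set(cfg.grid) | {cfg.all_or_nothing_level}
            off_grid = [
                o for o in sol.outcomes
                if not any(abs(o.coverage - g) < 1e-9 for g in grid)
            ]
            assert len(off_grid) <= 1  # only the marginal intervention

    def test_unit_weight_equity_scenario_equals_unweighted(self, fixture_records):
        cfg = u.AnalysisConfig(conversion_factor=4.3)
        s1 = u.solve_scenario(fixture_records, cfg)
        s2 = u.solve_scenario(
            fixture_records,
            cfg.with_(scenario="equity_weighted",
                      weights=u.EquityWeightSchedule.flat()),
        )
        assert s1.coverage_vector() == s2.coverage_vector()

    def test_cost_and_budget_scale_invariance(self, fixture_records):
        cfg = u.AnalysisConfig(conversion_factor=4.3)
        base = u.solve_scenario(fixture_records, cfg)
        scaled = u.solve_scenario(
            fixture_records,
            cfg.with_(conversion_factor=4.3 * 7.0, budget=cfg.budget * 7.0),
        )
        for i, c in base.coverage_vector().items():
            assert scaled.coverage_vector()[i] == pytest.approx(c, abs=1e-9)

    def test_marginal_icer_of_single_fully_funded_intervention(self):
        rec = _record("only", 1000, (1.0, 1.6, 1.9), (0.50, 0.80, 0.95))
        sol = u.solve_scenario([rec], u.AnalysisConfig(budget=1e7))
        assert sol.outcome("only").coverage == pytest.approx(1.0)
        # marginal ICER equals the last increment's ICER: 2/DALY per capita
        assert u.marginal_productivity(sol) == pytest.approx(2.0)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(u.UhcpackError):
            u.AnalysisConfig(scenario="scenario_9")

    def test_all_or_nothing_single_step_linear(self, fixture_records):
        cfg = u.AnalysisConfig(scenario="all_or_nothing", conversion_factor=4.3)
        ladders = build_ladders(fixture_records, cfg)
        for ladder in ladders:
            assert len(ladder.steps) == 1
            step = ladder.steps[0]
            assert step.theta_from == 0.0
            assert step.theta_to == pytest.approx(0.95)
            anchor_cost = ladder.record.anchor_cost[0.95]
            assert step.delta_cost == pytest.approx(
                anchor_cost * ladder.record.incident_population * 4.3
            )

    def test_all_or_nothing_weighting_splits_deciles(self, fixture_records):
        # linear benefit on (0, 0.95]: weighted/unweighted = 1.2/0.95
        cfg = u.AnalysisConfig(scenario="all_or_nothing")
        ladders = build_ladders(fixture_records, cfg)
        tb = next(l for l in ladders if l.id == "tb_dots")
        step = tb.steps[0]
        assert step.delta_weighted_benefit / step.delta_benefit == pytest.approx(
            1.2 / 0.95, abs=1e-9
        )

    def test_equity_scenario_ranks_on_weighted_benefits(self, fixture_records):
        cfg = u.AnalysisConfig(scenario="equity_weighted", conversion_factor=4.3)
        ladders = build_ladders(fixture_records, cfg)
        assert all(s.use_weighted for ladder in ladders for s in ladder.steps)


class TestCalibration:
    def test_all_covered_landmark_closed_form(self, two_linear_records):
        # the largest factor at which everything is affordable at 100% is
        # budget / total cost in source currency
        cfg = u.AnalysisConfig(budget=60_000.0)
        result = u.calibrate_conversion(
            two_linear_records,
            cfg,
            landmark=Landmark(all_covered=True, fractional_intervention_id=None,
                              coverage_band=None),
            bracket=(0.25, 25.0),
            coarse_points=120,
            tol=1e-6,
        )
        total_cost = 12_000.0  # (2.0 + 10.0) * 1000 at factor 1
        assert result.bracket[1] == pytest.approx(
            cfg.budget / total_cost, rel=1e-4
        )

    def test_calibration_is_self_consistent(self, fixture_records, base_config,
                                            calibration):
        cfg = base_config.with_(conversion_factor=calibration.factor)
        sol = u.solve_scenario(fixture_records, cfg)
        assert sol.fractional_intervention_id == "pneumonia_children"
        assert 0.70 < sol.fractional_coverage < 0.75

    def test_unattainable_landmark_reports_bracket_ends(self, two_linear_records):
        with pytest.raises(u.UhcpackError, match="terminal fractional"):
            u.calibrate_conversion(
                two_linear_records,
                u.AnalysisConfig(budget=1000.0),
                landmark=Landmark(fractional_intervention_id="nonexistent",
                                  coverage_band=(0.7, 0.75)),
                bracket=(0.5, 2.0),
                coarse_points=30,
            )
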