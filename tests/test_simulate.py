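"""Population draws, paired scenario simulation, budget impact and ICER."""

import numpy as np
import pytest

from marketce import (
    AnalysisConfig,
    MarketMix,
    PopulationSpec,
    RegimenEntry,
    ScenarioOutcomes,
    ScenarioSpec,
    Subgroup,
    SvrRange,
    TherapyProfile,
    budget_impact,
    draw_population,
    expenditure_per_svr,
    full_analysis,
    icer,
    pct_svr_summary,
    run_analysis,
    simulate_run,
)
from marketce.montecarlo import EmptySummaryError, derived_rng
from marketce.simulate import PairingError, apportion

GROUP = Subgroup("relapser", "GT1a", "none")


def one_cell_population(total: int) -> PopulationSpec:
    return PopulationSpec(
        total_range=(total, total),
        subtype_props={"GT1a": 1.0, "GT1b": 0.0},
        history_props={"relapser": 1.0, "partial_responder": 0.0, "null_responder": 0.0},
        cirrhosis_prop=0.0,
    )


def therapy(name, cost, svr, entrant=False):
    return TherapyProfile(
        name=name,
        entries={GROUP: RegimenEntry(name, (float(cost),), (12.0,), SvrRange(svr, svr))},
        is_new_entrant=entrant,
    )


class TestApportionment:
    def test_even_split_of_nine_respects_name_order(self):
        assert apportion(9, [0.5, 0.5]).tolist() == [5, 4]

    @pytest.mark.parametrize("total,shares", [(7, [0.2, 0.3, 0.5]), (95, [1 / 3] * 3), (1, [0.6, 0.4])])
    def test_counts_conserve_the_total(self, total, shares):
        counts = apportion(total, shares)
        assert counts.sum() == total and (counts >= 0).all()

    def test_vectorised_matches_scalar(self):
        totals = np.arange(1, 40)
        shares = [0.41, 0.09, 0.5]
        stacked = apportion(totals, shares)
        for i, t in enumerate(totals):
            assert stacked[i].tolist() == apportion(int(t), shares).tolist()


class TestPopulationDraws:
    def test_totals_stay_on_the_annual_range(self, population):
        rng = np.random.default_rng(0)
        _, totals, counts = draw_population(population, rng, size=5_000)
        assert totals.min() >= 90 and totals.max() <= 100
        assert (counts.sum(axis=1) == totals).all()

    def test_subtype_composition_recovered(self, population):
        rng = np.random.default_rng(1)
        groups, totals, counts = draw_population(population, rng, size=10_000)
        b_cols = [j for j, g in enumerate(groups) if g.subtype == "GT1b"]
        frac = counts[:, b_cols].sum() / totals.sum()
        se = np.sqrt(0.64 * 0.36 / totals.sum())
        assert abs(frac - 0.64) < 3 * se

    def test_degenerate_spec_concentrates_exactly(self):
        drawn = draw_population(one_cell_population(50), np.random.default_rng(2))
        assert drawn[GROUP] == 50
        assert sum(drawn.values()) == 50


class TestSimulateRun:
    def test_certain_cure_block_is_deterministic(self):
        mix = MarketMix({GROUP: {"a": 1.0}})
        result = simulate_run(mix, {GROUP: 10}, [therapy("a", 45_000, 1.0)], np.random.default_rng(0))
        assert result.n_svr == 10
        assert result.total_cost == 450_000
        assert result.n_treated == 10

    def test_binomial_success_mean(self):
        mix = MarketMix({GROUP: {"a": 1.0}})
        ther = [therapy("a", 1_000, 0.5)]
        rng = np.random.default_rng(3)
        draws = np.array(
            [simulate_run(mix, {GROUP: 100}, ther, rng).n_svr for _ in range(2_000)]
        )
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 50.0) < 3 * se

    def test_populated_subgroup_needs_market_share(self):
        other = Subgroup("null_responder", "GT1b", "compensated")
        mix = MarketMix({GROUP: {"a": 1.0}})
        with pytest.raises(Exception, match="no market share"):
            simulate_run(mix, {GROUP: 5, other: 5}, [therapy("a", 1_000, 0.5)], np.random.default_rng(0))


class TestPairedAnalysis:
    def toy_scenarios(self):
        mix_a = MarketMix({GROUP: {"a": 1.0}})
        mix_b = MarketMix({GROUP: {"b": 1.0}})
        return [ScenarioSpec(0, mix_a), ScenarioSpec(1, mix_b)]

    def toy_therapies(self):
        return [therapy("a", 32_800, 0.9), therapy("b", 45_000, 0.9, entrant=True)]

    def test_deterministic_given_master_seed(self, croatia):
        therapies, population, _ = croatia
        config = AnalysisConfig(n_runs=300, master_seed=5)
        first = full_analysis(therapies, population, config)
        second = full_analysis(therapies, population, config)
        for a, b in zip(first.outcomes, second.outcomes):
            assert np.array_equal(a.total_cost, b.total_cost)
            assert np.array_equal(a.n_svr, b.n_svr)

    def test_scenario_compared_with_itself_differs_nowhere(self, croatia):
        therapies, population, _ = croatia
        config = AnalysisConfig(n_runs=200, master_seed=5)
        baseline = full_analysis(therapies, population, config).scenarios[0]
        twin = ScenarioSpec(1, baseline.mix, frozenset())
        o0, o1 = run_analysis(therapies, population, [baseline, twin], config)
        assert np.array_equal(o0.total_cost, o1.total_cost)
        assert np.array_equal(o0.n_svr, o1.n_svr)

    def test_treated_counts_match_population_draws(self, croatia):
        therapies, population, _ = croatia
        config = AnalysisConfig(n_runs=250, master_seed=9)
        result = full_analysis(therapies, population, config)
        _, totals, _ = draw_population(
            population, derived_rng(config.master_seed, "population"), size=config.n_runs
        )
        for outcome in result.outcomes:
            assert np.array_equal(outcome.n_treated, totals)
            assert (outcome.n_svr <= outcome.n_treated).all()
            assert (outcome.n_svr >= 0).all()

    def test_cure_rates_rise_with_each_takeover_scenario(self, croatia):
        # the new entrant's SVR dominates every rival's in the built-in tables
        therapies, population, _ = croatia
        config = AnalysisConfig(n_runs=400, master_seed=3)
        result = full_analysis(therapies, population, config)
        means = [pct_svr_summary(o).mean for o in result.outcomes]
        assert means == sorted(means)

    def test_exact_budget_impact_on_a_deterministic_switch(self):
        # 10 patients move from a 32 800 to a 45 000 course
        config = AnalysisConfig(n_runs=50, master_seed=1)
        outcomes = run_analysis(
            self.toy_therapies(), one_cell_population(10), self.toy_scenarios(), config
        )
        impact = budget_impact(outcomes[1], outcomes[0])
        assert impact.delta_cost.mean == pytest.approx(122_000)
        assert impact.delta_cost.sd == 0.0
        assert impact.pct_increase == pytest.approx(100 * 122_000 / 328_000)

    def test_paired_run_identity(self, croatia):
        therapies, population, _ = croatia
        config = AnalysisConfig(n_runs=300, master_seed=13)
        outcomes = full_analysis(therapies, population, config).outcomes
        base = outcomes[0]
        for k in (1, 2, 3, 4):
            impact = budget_impact(outcomes[k], base)
            assert impact.delta_cost.mean + base.total_cost.mean() == pytest.approx(
                outcomes[k].total_cost.mean(), rel=1e-9
            )

    def test_unpaired_outcomes_are_rejected(self, croatia):
        therapies, population, _ = croatia
        a = full_analysis(therapies, population, AnalysisConfig(n_runs=100, master_seed=1)).outcomes
        b = full_analysis(therapies, population, AnalysisConfig(n_runs=100, master_seed=2)).outcomes
        with pytest.raises(PairingError):
            budget_impact(a[1], b[0])


class TestRatios:
    def make_outcomes(self, scenario_id, cost, svr, n=4):
        return ScenarioOutcomes(
            scenario_id=scenario_id,
            total_cost=np.full(n, float(cost)),
            n_treated=np.full(n, 100),
            n_svr=np.full(n, float(svr)),
            pairing_token=("t", n),
        )

    def test_expenditure_per_svr_identity(self):
        outcome = self.make_outcomes(0, 450_000, 10)
        summary = expenditure_per_svr(outcome)
        assert summary.mean == pytest.approx(45_000)
        assert summary.mean * 10 == pytest.approx(450_000)

    def test_zero_success_runs_are_excluded(self):
        outcome = ScenarioOutcomes(
            0, np.array([100.0, 200.0]), np.array([10, 10]), np.array([0.0, 4.0]), ("t",)
        )
        summary = expenditure_per_svr(outcome)
        assert summary.n_excluded == 1 and summary.mean == pytest.approx(50.0)
        all_zero = ScenarioOutcomes(0, np.array([100.0]), np.array([10]), np.array([0.0]), ("t",))
        with pytest.raises(EmptySummaryError):
            expenditure_per_svr(all_zero)

    def test_icer_is_ratio_of_mean_deltas(self):
        base = self.make_outcomes(0, 1_000_000, 50)
        expanded = self.make_outcomes(1, 1_250_000, 62.5)
        result = icer(expanded, base)
        assert result.defined
        assert result.icer == pytest.approx(250_000 / 12.5)
        assert result.icer * result.delta_svr_mean == pytest.approx(result.delta_cost_mean)

    def test_icer_zero_cost_expansion(self):
        base = self.make_outcomes(0, 500_000, 40)
        expanded = self.make_outcomes(1, 500_000, 55)
        assert icer(expanded, base).icer == 0.0

    def test_dominated_expansion_is_tagged_not_raised(self):
        base = self.make_outcomes(0, 500_000, 40)
        worse = self.make_outcomes(1, 600_000, 40)
        result = icer(worse, base)
        assert not result.defined and np.isnan(result.icer)
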