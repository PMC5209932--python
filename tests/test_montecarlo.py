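"""Sampling, cost per SVR, the closed-form oracle, and savings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from marketce import (
    AnalysisConfig,
    RegimenEntry,
    Subgroup,
    SvrRange,
    analytic_mean_cost_per_svr,
    cost_per_svr,
    mc_cost_per_svr,
    sample_course_cost,
    sample_svr,
    savings_per_svr,
)
from marketce.montecarlo import (
    EligibilityError,
    EmptySummaryError,
    OracleUnavailableError,
    analytic_cost_per_svr_bounds,
    ce_table,
)

CONFIG = AnalysisConfig(n_runs=10_000, master_seed=42)


def entry(costs, svr_lo, svr_hi, name="x"):
    return RegimenEntry(
        therapy_name=name,
        course_costs=tuple(costs),
        durations=tuple(24.0 for _ in costs),
        svr=SvrRange(svr_lo, svr_hi),
    )


class TestSamplers:
    def test_point_svr_always_returns_the_point(self):
        rng = np.random.default_rng(0)
        draws = sample_svr(SvrRange(0.959, 0.959), rng, size=1000)
        assert np.all(draws == 0.959)

    def test_uniform_draws_stay_in_bounds_with_matching_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_svr(SvrRange(0.38, 0.39), rng, size=10_000)
        assert draws.min() >= 0.38 and draws.max() <= 0.39
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.385) < 3 * se

    def test_zero_floor_interval_may_draw_near_zero(self):
        rng = np.random.default_rng(0)
        draws = sample_svr(SvrRange(0.0, 0.08), rng, size=10_000)
        assert draws.min() >= 0.0 and draws.max() <= 0.08

    def test_single_cost_variant_is_deterministic(self):
        rng = np.random.default_rng(0)
        assert sample_course_cost(entry([45_000], 0.9, 0.9), rng) == 45_000

    def test_two_variant_cost_draws_each_printed_value(self):
        rng = np.random.default_rng(0)
        draws = sample_course_cost(entry([30_200, 34_300], 0.6, 0.8), rng, size=10_000)
        assert set(np.unique(draws)) == {30_200, 34_300}

    def test_fair_variant_split_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_course_cost(entry([4_200, 8_400], 0.3, 0.5), rng, size=10_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 6_300) < 3 * se

    def test_ineligible_entry_refused(self):
        bad = RegimenEntry("x", eligible=False)
        with pytest.raises(EligibilityError):
            sample_course_cost(bad, np.random.default_rng(0))


class TestCostPerSvr:
    @pytest.mark.parametrize(
        "cost,svr,expected",
        [(45_000, 0.959, 46_923.879), (41_900, 0.385, 108_831.169), (12_345, 1.0, 12_345.0)],
    )
    def test_direct_division(self, cost, svr, expected):
        assert cost_per_svr(cost, svr) == pytest.approx(expected, abs=0.001)

    def test_zero_svr_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cost_per_svr(1000.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cost=st.floats(1e2, 1e6),
        svr=st.floats(0.01, 1.0),
        d_cost=st.floats(1.0, 1e5),
        d_svr=st.floats(0.001, 0.5),
    )
    def test_monotone_in_cost_and_svr(self, cost, svr, d_cost, d_svr):
        assert cost_per_svr(cost + d_cost, svr) > cost_per_svr(cost, svr)
        if svr + d_svr <= 1.0:
            assert cost_per_svr(cost, svr + d_svr) < cost_per_svr(cost, svr)


class TestClosedFormOracle:
    def test_matches_numeric_integration(self):
        # E[1/SVR] for U(a, b) by quadrature, an independent route
        for costs, a, b in [((41_900,), 0.38, 0.39), ((4_200, 8_400), 0.35, 0.50)]:
            e_inv = quad(lambda s: (1 / s) / (b - a), a, b)[0]
            expected = float(np.mean(costs)) * e_inv
            assert analytic_mean_cost_per_svr(entry(costs, a, b)) == pytest.approx(expected, rel=1e-9)

    def test_frozen_values(self):
        # 41900 * ln(0.39/0.38)/0.01 and 6300 * ln(0.50/0.35)/0.15
        assert analytic_mean_cost_per_svr(entry([41_900], 0.38, 0.39)) == pytest.approx(108_837.29, abs=0.01)
        assert analytic_mean_cost_per_svr(entry([4_200, 8_400], 0.35, 0.50)) == pytest.approx(14_980.35, abs=0.01)

    def test_degenerate_limit_is_direct_division(self):
        assert analytic_mean_cost_per_svr(entry([45_000], 0.959, 0.959)) == pytest.approx(45_000 / 0.959)

    def test_unavailable_at_zero_floor(self):
        with pytest.raises(OracleUnavailableError):
            analytic_mean_cost_per_svr(entry([41_900], 0.0, 0.34))


class TestMonteCarloEngine:
    def test_degenerate_cell_collapses_to_exact_ratio(self):
        summary = mc_cost_per_svr(entry([45_000], 0.959, 0.959), CONFIG)
        assert summary.sd == 0.0
        assert summary.mean == summary.min == summary.max == pytest.approx(45_000 / 0.959)

    def test_mc_mean_agrees_with_oracle_for_every_eligible_cell(self, therapies):
        checked = 0
        for therapy in therapies:
            for group in Subgroup.lattice():
                if not therapy.is_eligible(group):
                    continue
                cell = therapy.entry(group)
                if cell.svr.low <= 0:
                    continue
                summary = mc_cost_per_svr(cell, CONFIG, group=group)
                expected = analytic_mean_cost_per_svr(cell)
                se = summary.sd / np.sqrt(summary.n_runs) if summary.sd else 1e-6
                assert abs(summary.mean - expected) < max(3 * se, 1e-6), (therapy.name, group.label)
                lo, hi = analytic_cost_per_svr_bounds(cell)
                assert lo - 1e-9 <= summary.min <= summary.max <= hi + 1e-9
                checked += 1
        assert checked > 60

    def test_bit_identical_summaries_for_same_seed(self):
        cell = entry([23_200, 32_700], 0.52, 0.67)
        group = Subgroup("naive", "GT1a", "none")
        a = mc_cost_per_svr(cell, CONFIG, group=group)
        b = mc_cost_per_svr(cell, CONFIG, group=group)
        assert a == b

    def test_no_exclusions_under_continuous_sampling(self, therapies):
        # zero-SVR draws have probability zero even for ranges touching 0
        boc = next(t for t in therapies if t.name == "BOC+pegIFN")
        group = Subgroup("null_responder", "GT1a", "compensated")
        summary = mc_cost_per_svr(boc.entry(group), CONFIG, group=group)
        assert summary.n_excluded == 0

    def test_all_zero_svr_cell_has_no_summary(self):
        with pytest.raises(EmptySummaryError):
            mc_cost_per_svr(entry([1_000], 0.0, 0.0), CONFIG)


class TestSavings:
    GROUP = Subgroup("null_responder", "GT1a", "none")

    def test_self_comparison_gives_zero_savings(self):
        cell = entry([45_000], 0.9, 1.0)
        result = savings_per_svr(cell, cell, CONFIG, group=self.GROUP)
        assert result.savings.mean == 0.0 and result.savings.sd == 0.0

    def test_new_vs_boc_null_responders(self, therapies, new_entrant):
        boc = next(t for t in therapies if t.name == "BOC+pegIFN")
        result = savings_per_svr(
            new_entrant.entry(self.GROUP), boc.entry(self.GROUP), CONFIG, group=self.GROUP
        )
        expected = analytic_mean_cost_per_svr(boc.entry(self.GROUP)) - 45_000 / 0.954
        se = result.savings.sd / np.sqrt(result.savings.n_runs)
        assert expected == pytest.approx(61_666, abs=5)
        assert abs(result.savings.mean - expected) < 3 * se
        assert result.savings.min <= result.savings.mean <= result.savings.max

    def test_paired_savings_mean_decomposes_into_cell_means(self, therapies, new_entrant):
        # common random numbers: mean savings == rival mean - entrant mean
        sim = next(t for t in therapies if t.name == "SIM+pegIFN")
        result = savings_per_svr(
            new_entrant.entry(self.GROUP), sim.entry(self.GROUP), CONFIG, group=self.GROUP
        )
        rival = mc_cost_per_svr(sim.entry(self.GROUP), CONFIG, group=self.GROUP)
        mine = mc_cost_per_svr(new_entrant.entry(self.GROUP), CONFIG, group=self.GROUP)
        assert result.savings.mean == pytest.approx(rival.mean - mine.mean, abs=1e-6)


def test_ce_table_covers_eligible_cells_only(therapies):
    cells = ce_table(therapies, AnalysisConfig(n_runs=100, master_seed=1))
    keys = {(c.therapy_name, c.subgroup) for c in cells}
    # 5 therapies x 16 cells minus the 12 ineligible dual-therapy cells
    assert len(cells) == 5 * 16 - 12
    for therapy in therapies:
        for group in Subgroup.lattice():
            assert ((therapy.name, group) in keys) == therapy.is_eligible(group)
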