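"""End-to-end orchestration: tables -> tiers -> scenarios -> outcomes.

`full_analysis` runs the whole chain on one input set and returns every
intermediate product, so the command-line interface, the analysis scripts
and the reproduction checks all share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import AnalysisConfig, PopulationSpec, Subgroup, TherapyProfile, validate_inputs
from .montecarlo import (
    CECell,
    SavingsCell,
    ce_table,
    ce_table_frame,
    savings_table,
    savings_table_frame,
)
from .scenarios import (
    MarketMix,
    ScenarioSpec,
    TierAssignment,
    baseline_mix,
    build_scenarios,
    classify_cell,
    mix_frame,
    tier_frame,
)
from .simulate import ScenarioOutcomes, run_analysis, runs_frame, summary_frame

__all__ = ["AnalysisResult", "full_analysis", "reproduction_metrics"]


@dataclass(frozen=True)
class AnalysisResult:
    """Everything one full pipeline run produces."""

    therapies: tuple[TherapyProfile, ...]
    population: PopulationSpec
    config: AnalysisConfig
    ce_cells: list[CECell]
    savings_cells: list[SavingsCell]
    assignments: list[TierAssignment]
    baseline: MarketMix
    scenarios: list[ScenarioSpec]
    outcomes: list[ScenarioOutcomes]

    def ce_frame(self) -> pd.DataFrame:
        return ce_table_frame(self.ce_cells, self.config.reporting_rounding)

    def savings_frame(self) -> pd.DataFrame:
        return savings_table_frame(self.savings_cells, self.config.reporting_rounding)

    def tier_frame(self) -> pd.DataFrame:
        return tier_frame(self.assignments)

    def mix_frame(self) -> pd.DataFrame:
        return mix_frame(self.scenarios)

    def summary_frame(self) -> pd.DataFrame:
        return summary_frame(self.outcomes, self.config.reporting_rounding)

    def runs_frame(self) -> pd.DataFrame:
        return runs_frame(self.outcomes)


def full_analysis(
    therapies: Sequence[TherapyProfile],
    population: PopulationSpec,
    config: AnalysisConfig,
    mode: str = "binomial",
) -> AnalysisResult:
    """Run cost-effectiveness, tier classification, scenario construction
    and the paired outcome simulation on one input set."""
    therapies = tuple(therapies)
    validate_inputs(therapies, population)
    entrant = next(t for t in therapies if t.is_new_entrant)

    experienced = tuple(
        g for g in Subgroup.experienced()
        if g in entrant.entries  # cells the new entrant is analysed on
    )
    ce_cells = ce_table(therapies, config)  # full lattice, incl. naive comparisons
    savings_cells = savings_table(therapies, config, groups=experienced)
    assignments = [classify_cell(c, config.tier3_threshold) for c in savings_cells]
    baseline = baseline_mix(
        therapies,
        ce_cells=[c for c in ce_cells if c.subgroup in experienced],
        strategy=config.baseline_strategy,
        groups=experienced,
    )
    scenarios = build_scenarios(assignments, baseline, entrant.name)
    outcomes = run_analysis(therapies, population, scenarios, config, mode=mode)
    return AnalysisResult(
        therapies=therapies,
        population=population,
        config=config,
        ce_cells=ce_cells,
        savings_cells=savings_cells,
        assignments=assignments,
        baseline=baseline,
        scenarios=scenarios,
        outcomes=outcomes,
    )


def reproduction_metrics(result: AnalysisResult) -> dict[str, float]:
    """Headline quantities of one analysis run, keyed like the published
    case-study reference values (cost/SVR cells at the reporting rounding,
    percentages on the 0-100 scale, budget impact in million EUR)."""
    from .model import round_to_granularity
    from .simulate import budget_impact, icer, pct_svr_summary

    rounding = result.config.reporting_rounding
    cps = {(c.therapy_name, c.subgroup.label): c.cost_per_svr.mean for c in result.ce_cells}
    entrant = next(t for t in result.therapies if t.is_new_entrant).name
    by_id = {o.scenario_id: o for o in result.outcomes}
    base = by_id[0]
    bia4 = budget_impact(by_id[4], base)
    metrics = {
        "cps_new_naive_1a_nocirr": cps[(entrant, "naive/GT1a/none")],
        "cps_new_relapser_1a_nocirr": cps[(entrant, "relapser/GT1a/none")],
        "cps_new_null_1a_nocirr": cps[(entrant, "null_responder/GT1a/none")],
        "cps_new_partial_1b_cirr": cps[(entrant, "partial_responder/GT1b/compensated")],
        "cps_boc_null_nocirr": cps[("BOC+pegIFN", "null_responder/GT1a/none")],
        "pct_svr_scenario0": pct_svr_summary(base).mean,
        "pct_svr_scenario1": pct_svr_summary(by_id[1]).mean,
        "pct_svr_scenario4": pct_svr_summary(by_id[4]).mean,
        "pct_cost_increase_scenario4": bia4.pct_increase,
        "delta_cost_scenario4_meur": bia4.delta_cost.mean / 1e6,
        "icer_scenario1": icer(by_id[1], base).icer,
        "icer_scenario4": icer(by_id[4], base).icer,
    }
    for key in list(metrics):
        if key.startswith("cps_"):
            metrics[key] = round_to_granularity(metrics[key], rounding)
    return metrics
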