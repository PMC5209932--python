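"""Takeover tiers and nested market-mix scenarios.

The order in which the new entrant should claim market cells is decided by
its simulated savings per SVR against the rival occupying each
(subgroup, rival) cell:

* tier 1 - the new entrant is cheaper per SVR in *every* simulated run
  (savings minimum > 0);
* tier 2 - cheaper on average, but some runs go the other way
  (savings mean > 0, minimum <= 0);
* tier 3 - more expensive on average, by at most the configured threshold
  (default EUR 10 000; boundary inclusive);
* tier 4 - everything else.

Scenario k (k = 1..4) hands the new entrant the baseline shares of every
cell with tier <= k; scenario 0 is the pre-entry market.  Takeover sets are
therefore nested by construction, and scenario 4 is full takeover.

The pre-entry market mix is not an observable input here; two stylised
strategies are provided.  ``cheapest_per_svr`` gives each subgroup's whole
share to the rival with the lowest mean cost per SVR (rational single-payer
assumption; ties broken alphabetically); ``equal_eligible`` splits shares
equally across eligible rivals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import AnalysisConfig, InputError, Subgroup, TherapyProfile
from .montecarlo import CECell, SavingsCell, ce_table, savings_table

__all__ = [
    "ConfigurationError",
    "IncompleteClassificationError",
    "TierAssignment",
    "MarketMix",
    "ScenarioSpec",
    "baseline_mix",
    "classify_cell",
    "classify_market",
    "build_scenarios",
    "tier_frame",
    "mix_frame",
]

_SHARE_TOL = 1e-9


class ConfigurationError(InputError):
    """A market mix cannot be built (e.g. a subgroup with no eligible rival)."""


class IncompleteClassificationError(InputError):
    """A takeover cell is missing its tier assignment."""


@dataclass(frozen=True)
class TierAssignment:
    subgroup: Subgroup
    rival_name: str
    tier: int

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3, 4):
            raise InputError(f"tier must be 1-4, got {self.tier}")


@dataclass(frozen=True)
class MarketMix:
    """Per-subgroup therapy shares; each subgroup's shares sum to 1."""

    shares: Mapping[Subgroup, Mapping[str, float]]

    def __post_init__(self) -> None:
        clean: dict[Subgroup, dict[str, float]] = {}
        for group, by_therapy in self.shares.items():
            if any(s < -_SHARE_TOL for s in by_therapy.values()):
                raise InputError(f"subgroup {group.label}: negative market share")
            total = sum(by_therapy.values())
            if abs(total - 1.0) > 1e-6:
                raise InputError(
                    f"subgroup {group.label}: shares sum to {total}, expected 1"
                )
            clean[group] = {n: s for n, s in by_therapy.items() if s > _SHARE_TOL}
        object.__setattr__(self, "shares", clean)

    def share(self, group: Subgroup, therapy_name: str) -> float:
        return self.shares.get(group, {}).get(therapy_name, 0.0)

    @property
    def subgroups(self) -> tuple[Subgroup, ...]:
        return tuple(sorted(self.shares, key=lambda g: g.sort_index))


@dataclass(frozen=True)
class ScenarioSpec:
    """One market-entry scenario: its mix and the cells taken over."""

    scenario_id: int
    mix: MarketMix
    takeover_set: frozenset[tuple[Subgroup, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.scenario_id <= 4):
            raise InputError(f"scenario_id must be 0-4, got {self.scenario_id}")
        object.__setattr__(self, "takeover_set", frozenset(self.takeover_set))


def baseline_mix(
    therapies: Sequence[TherapyProfile],
    ce_cells: Sequence[CECell] | None = None,
    strategy: str = "cheapest_per_svr",
    groups: Iterable[Subgroup] | None = None,
    config: AnalysisConfig | None = None,
) -> MarketMix:
    """Pre-entry market mix over the experienced subgroups.

    ``cheapest_per_svr`` needs a cost-effectiveness table; one is computed
    from ``config`` if not supplied.  The new entrant holds no share.
    """
    groups = tuple(groups) if groups is not None else Subgroup.experienced()
    rivals = [t for t in therapies if not t.is_new_entrant]
    shares: dict[Subgroup, dict[str, float]] = {}
    if strategy == "cheapest_per_svr":
        if ce_cells is None:
            ce_cells = ce_table(therapies, config or AnalysisConfig(), groups=groups)
        mean_cps = {(c.therapy_name, c.subgroup): c.cost_per_svr.mean for c in ce_cells}
    for group in groups:
        eligible = sorted(t.name for t in rivals if t.is_eligible(group))
        if not eligible:
            raise ConfigurationError(
                f"subgroup {group.label}: no eligible rival therapy for the baseline"
            )
        if strategy == "equal_eligible":
            shares[group] = {name: 1.0 / len(eligible) for name in eligible}
        elif strategy == "cheapest_per_svr":
            missing = [n for n in eligible if (n, group) not in mean_cps]
            if missing:
                raise ConfigurationError(
                    f"subgroup {group.label}: cost-per-SVR table misses {missing}"
                )
            # min() is stable, so alphabetical order breaks exact ties
            winner = min(eligible, key=lambda n: mean_cps[(n, group)])
            shares[group] = {winner: 1.0}
        else:
            raise ConfigurationError(f"unknown baseline strategy {strategy!r}")
    return MarketMix(shares)


def classify_cell(savings: SavingsCell, threshold: float = 10_000.0) -> TierAssignment:
    """Assign a takeover tier from a cell's savings-per-SVR summary."""
    s = savings.savings
    if s.min > 0:
        tier = 1
    elif s.mean > 0:
        tier = 2
    elif s.mean >= -threshold:  # boundary inclusive at exactly -threshold
        tier = 3
    else:
        tier = 4
    return TierAssignment(subgroup=savings.subgroup, rival_name=savings.rival_name, tier=tier)


def classify_market(
    therapies: Sequence[TherapyProfile],
    config: AnalysisConfig,
    groups: Iterable[Subgroup] | None = None,
) -> list[TierAssignment]:
    """Tier for every eligible experienced (subgroup, rival) cell."""
    groups = tuple(groups) if groups is not None else Subgroup.experienced()
    cells = savings_table(therapies, config, groups=groups)
    return [classify_cell(c, config.tier3_threshold) for c in cells]


def build_scenarios(
    assignments: Sequence[TierAssignment],
    baseline: MarketMix,
    new_entrant_name: str,
) -> list[ScenarioSpec]:
    """The five nested scenarios (0 = pre-entry market, 4 = full takeover).

    Scenario k reassigns to the new entrant the baseline share of every
    assigned cell with tier <= k.  Every cell holding baseline share must be
    classified.
    """
    tier_of = {(a.subgroup, a.rival_name): a.tier for a in assignments}
    for group in baseline.subgroups:
        for rival in baseline.shares[group]:
            if rival != new_entrant_name and (group, rival) not in tier_of:
                raise IncompleteClassificationError(
                    f"cell ({group.label}, {rival}) holds baseline share but has "
                    f"no tier assignment"
                )
    scenarios = [ScenarioSpec(0, baseline, frozenset())]
    for k in (1, 2, 3, 4):
        taken = frozenset(cell for cell, tier in tier_of.items() if tier <= k)
        shares: dict[Subgroup, dict[str, float]] = {}
        for group in baseline.subgroups:
            new_shares = dict(baseline.shares[group])
            moved = 0.0
            for rival in list(new_shares):
                if (group, rival) in taken:
                    moved += new_shares.pop(rival)
            if moved > 0:
                new_shares[new_entrant_name] = new_shares.get(new_entrant_name, 0.0) + moved
            shares[group] = new_shares
        scenarios.append(ScenarioSpec(k, MarketMix(shares), taken))
    return scenarios


def tier_frame(assignments: Sequence[TierAssignment]) -> pd.DataFrame:
    """Tidy tier-assignment table."""
    return pd.DataFrame(
        [
            {
                "history": a.subgroup.history,
                "subtype": a.subgroup.subtype,
                "cirrhosis": a.subgroup.cirrhosis,
                "rival": a.rival_name,
                "tier": a.tier,
            }
            for a in sorted(assignments, key=lambda a: (a.subgroup.sort_index, a.rival_name))
        ]
    )


def mix_frame(scenarios: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Tidy per-scenario market-share table."""
    rows = []
    for spec in scenarios:
        for group in spec.mix.subgroups:
            for therapy, share in sorted(spec.mix.shares[group].items()):
                rows.append(
                    {
                        "scenario": spec.scenario_id,
                        "history": group.history,
                        "subtype": group.subtype,
                        "cirrhosis": group.cirrhosis,
                        "therapy": therapy,
                        "share": share,
                    }
                )
    return pd.DataFrame(rows)
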