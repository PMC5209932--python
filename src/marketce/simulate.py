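"""Population-level scenario simulation: budget impact, SVR counts, ICER.

Each Monte Carlo run draws one annual experienced population (total uniform
over the configured integer range, allocated to the twelve experienced
lattice cells by a single multinomial draw under the independence
assumption of :class:`~marketce.model.PopulationSpec`) and one set of
(SVR, course-cost) samples per (therapy, subgroup) cell.  Those draws are
shared by every scenario - common random numbers - so per-run differences
between scenarios isolate the market-mix change.

Within a scenario run, each subgroup's patients are apportioned to the
therapies holding market share by largest-remainder rounding (ties broken
by therapy name order); successes in a (therapy, subgroup) block are
binomial in the block size and the sampled SVR.  The binomial draw is
inverted from a per-cell uniform shared across scenarios (inverse-CDF
coupling), so two scenarios that treat a block identically obtain
identical successes, and comparing a scenario against itself yields
exactly zero differences.  An ``expectation`` mode replaces the binomial
draw with its mean (block size x SVR) for variance-free checks.

Budget impact is the per-run cost difference against scenario 0; the ICER
is the ratio of mean cost difference to mean difference in patients
achieving SVR (ratio of paired-run means, the standard health-economics
convention; per-run ratios are unstable when the SVR difference is small).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .model import (
    AnalysisConfig,
    DistributionSummary,
    PopulationSpec,
    Subgroup,
    TherapyProfile,
)
from .montecarlo import _cell_draws, derived_rng, sample_course_cost, sample_svr
from .scenarios import ConfigurationError, MarketMix, ScenarioSpec

__all__ = [
    "PairingError",
    "RunResult",
    "ScenarioOutcomes",
    "BudgetImpact",
    "IcerResult",
    "apportion",
    "draw_population",
    "simulate_run",
    "run_analysis",
    "budget_impact",
    "expenditure_per_svr",
    "pct_svr_summary",
    "icer",
    "summary_frame",
    "runs_frame",
]


class PairingError(ValueError):
    """Outcome sets do not come from the same paired simulation."""


@dataclass(frozen=True)
class RunResult:
    """Totals for one scenario in one simulation run."""

    scenario_id: int
    run_index: int
    total_cost: float
    n_treated: int
    n_svr: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_svr <= self.n_treated):
            raise ValueError(
                f"run {self.run_index}: n_svr={self.n_svr} outside [0, {self.n_treated}]"
            )
        if self.total_cost < 0:
            raise ValueError(f"run {self.run_index}: negative total cost")


@dataclass(frozen=True)
class ScenarioOutcomes:
    """Per-run totals for one scenario, paired across scenarios.

    ``pairing_token`` identifies the paired simulation (seed lineage and run
    count); cross-scenario comparisons require equal tokens.
    """

    scenario_id: int
    total_cost: np.ndarray
    n_treated: np.ndarray
    n_svr: np.ndarray
    pairing_token: tuple = ()

    @property
    def n_runs(self) -> int:
        return len(self.total_cost)

    @property
    def pct_svr(self) -> np.ndarray:
        """Per-run percentage of treated patients achieving SVR."""
        return 100.0 * self.n_svr / self.n_treated

    def runs(self) -> list[RunResult]:
        return [
            RunResult(self.scenario_id, i, float(self.total_cost[i]),
                      int(self.n_treated[i]), float(self.n_svr[i]))
            for i in range(self.n_runs)
        ]


@dataclass(frozen=True)
class BudgetImpact:
    """Cost difference of a scenario against the pre-entry market."""

    scenario_id: int
    delta_cost: DistributionSummary
    pct_increase: float  # mean delta / mean baseline cost, in %


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness ratio of a scenario vs scenario 0.

    ``icer`` is mean(delta cost) / mean(delta SVR count) over paired runs;
    undefined (``defined=False``, NaN) when the mean SVR gain is not
    positive - the expansion is then dominated or effect-neutral.
    """

    scenario_id: int
    delta_cost_mean: float
    delta_svr_mean: float
    icer: float
    defined: bool
    delta_cost: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    delta_svr: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def _summary(values: np.ndarray, n_excluded: int = 0) -> DistributionSummary:
    return DistributionSummary(
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        sd=float(values.std()),
        n_runs=int(values.size) + n_excluded,
        n_excluded=n_excluded,
    )


def apportion(totals, shares: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of integer totals to shares.

    ``totals`` may be a scalar or a vector of per-run totals; returns an
    integer array of shape (n_runs, n_shares) (or (n_shares,) for a
    scalar).  Remainder ties are resolved in favour of earlier positions,
    which callers arrange to be therapy-name order.
    """
    scalar = np.isscalar(totals)
    totals_arr = np.atleast_1d(np.asarray(totals, dtype=np.int64))
    shares_arr = np.asarray(shares, dtype=float)
    quotas = totals_arr[:, None] * shares_arr[None, :]
    base = np.floor(quotas + 1e-12).astype(np.int64)
    short = totals_arr - base.sum(axis=1)
    frac = quotas - base
    order = np.argsort(-frac, axis=1, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(shares_arr.size)[None, :], axis=1)
    counts = base + (rank < short[:, None])
    return counts[0] if scalar else counts


def draw_population(
    spec: PopulationSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw annual experienced populations.

    The total is uniform on the integer range; allocation over the twelve
    experienced cells is one multinomial draw.  With ``size=None`` returns a
    single ``{Subgroup: count}`` mapping, otherwise ``(groups, totals,
    counts)`` with ``counts`` of shape (size, 12).
    """
    probs = spec.cell_probabilities()
    groups = tuple(sorted(probs, key=lambda g: g.sort_index))
    pvals = np.array([probs[g] for g in groups])
    pvals = pvals / pvals.sum()
    lo, hi = spec.total_range
    if size is None:
        total = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(total, pvals)
        return {g: int(c) for g, c in zip(groups, counts)}
    totals = rng.integers(lo, hi + 1, size=size)
    counts = rng.multinomial(totals, pvals)
    return groups, totals, counts


def _block_successes(counts, svrs, luck, mode: str):
    """Successes for (therapy, subgroup) blocks of given sizes.

    ``binomial`` inverts the binomial CDF at a shared uniform, coupling
    scenarios; ``expectation`` returns the binomial mean.
    """
    if mode == "expectation":
        return np.asarray(counts, dtype=float) * np.asarray(svrs, dtype=float)
    if mode != "binomial":
        raise ValueError(f"unknown simulation mode {mode!r}")
    return binom.ppf(luck, np.asarray(counts), np.asarray(svrs))


def simulate_run(
    mix: MarketMix,
    population: Mapping[Subgroup, int],
    therapies: Sequence[TherapyProfile],
    rng: np.random.Generator,
    mode: str = "binomial",
    first_variant_prob: float = 0.5,
) -> RunResult:
    """One simulation run of one market mix (reference single-run path)."""
    by_name = {t.name: t for t in therapies}
    total_cost = 0.0
    n_treated = 0
    n_svr = 0.0
    for group in sorted(population, key=lambda g: g.sort_index):
        patients = population[group]
        if patients == 0:
            continue
        shares = mix.shares.get(group, {})
        if not shares or sum(shares.values()) <= 0:
            raise ConfigurationError(
                f"subgroup {group.label} is populated but holds no market share"
            )
        names = sorted(shares)
        counts = apportion(patients, [shares[n] for n in names])
        for name, count in zip(names, counts):
            entry = by_name[name].entry(group)
            svr = sample_svr(entry.svr, rng)
            cost = sample_course_cost(entry, rng, first_variant_prob=first_variant_prob)
            luck = rng.random()
            successes = float(_block_successes(count, svr, luck, mode))
            total_cost += count * cost
            n_treated += int(count)
            n_svr += successes
    return RunResult(0, 0, total_cost, n_treated, n_svr)


def run_analysis(
    therapies: Sequence[TherapyProfile],
    population: PopulationSpec,
    scenarios: Sequence[ScenarioSpec],
    config: AnalysisConfig,
    mode: str = "binomial",
) -> list[ScenarioOutcomes]:
    """Paired Monte Carlo simulation of every scenario.

    All scenarios share, per run index, one population draw and one
    (SVR, cost, binomial-uniform) draw per (therapy, subgroup) cell, so
    scenario contrasts are common-random-number paired.  Deterministic
    given ``config.master_seed``.
    """
    by_name = {t.name: t for t in therapies}
    n_runs = config.n_runs

    pop_rng = derived_rng(config.master_seed, "population")
    groups, totals, pop_counts = draw_population(population, pop_rng, size=n_runs)
    col = {g: j for j, g in enumerate(groups)}

    # Cells used by any scenario: draws and coupling uniforms, shared across scenarios.
    used: set[tuple[str, Subgroup]] = set()
    for spec in scenarios:
        for group in spec.mix.subgroups:
            for name in spec.mix.shares[group]:
                used.add((name, group))
    draws: dict[tuple[str, Subgroup], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name, group in sorted(used, key=lambda k: (k[0], k[1].sort_index)):
        entry = by_name[name].entry(group)
        svrs, costs = _cell_draws(entry, config, group, None)
        luck = derived_rng(config.master_seed, "luck", name, group.label).random(n_runs)
        draws[(name, group)] = (svrs, costs, luck)

    token = ("paired", config.master_seed, n_runs, mode)
    outcomes = []
    for spec in scenarios:
        total_cost = np.zeros(n_runs)
        n_treated = np.zeros(n_runs, dtype=np.int64)
        n_svr = np.zeros(n_runs)
        for group in groups:
            shares = spec.mix.shares.get(group, {})
            if not shares:
                if pop_counts[:, col[group]].any():
                    raise ConfigurationError(
                        f"scenario {spec.scenario_id}: subgroup {group.label} is "
                        f"populated but holds no market share"
                    )
                continue
            names = sorted(shares)
            counts = apportion(pop_counts[:, col[group]], [shares[n] for n in names])
            for j, name in enumerate(names):
                svrs, costs, luck = draws[(name, group)]
                block = counts[:, j]
                total_cost += block * costs
                n_treated += block
                n_svr += _block_successes(block, svrs, luck, mode)
        outcomes.append(
            ScenarioOutcomes(spec.scenario_id, total_cost, n_treated, n_svr, token)
        )
    return outcomes


def _check_paired(a: ScenarioOutcomes, b: ScenarioOutcomes) -> None:
    if a.pairing_token != b.pairing_token or a.n_runs != b.n_runs:
        raise PairingError(
            "outcome sets are not paired (different seed lineage or run count)"
        )


def budget_impact(outcomes_k: ScenarioOutcomes, outcomes_0: ScenarioOutcomes) -> BudgetImpact:
    """Per-run cost difference of scenario k against the pre-entry market."""
    _check_paired(outcomes_k, outcomes_0)
    delta = outcomes_k.total_cost - outcomes_0.total_cost
    baseline_mean = outcomes_0.total_cost.mean()
    return BudgetImpact(
        scenario_id=outcomes_k.scenario_id,
        delta_cost=_summary(delta),
        pct_increase=100.0 * float(delta.mean()) / float(baseline_mean),
    )


def expenditure_per_svr(outcomes: ScenarioOutcomes) -> DistributionSummary:
    """Per-run total cost per patient achieving SVR.

    Runs with zero successes have no finite ratio; they are excluded and
    counted in ``n_excluded``.
    """
    ok = outcomes.n_svr > 0
    values = outcomes.total_cost[ok] / outcomes.n_svr[ok]
    if values.size == 0:
        from .montecarlo import EmptySummaryError

        raise EmptySummaryError("every run had zero successes")
    return _summary(values, n_excluded=int((~ok).sum()))


def pct_svr_summary(outcomes: ScenarioOutcomes) -> DistributionSummary:
    """Summary of the per-run percentage of patients achieving SVR."""
    return _summary(outcomes.pct_svr)


def icer(outcomes_k: ScenarioOutcomes, outcomes_0: ScenarioOutcomes) -> IcerResult:
    """ICER of scenario k vs scenario 0: mean Δcost / mean ΔSVR (paired)."""
    _check_paired(outcomes_k, outcomes_0)
    delta_cost = outcomes_k.total_cost - outcomes_0.total_cost
    delta_svr = outcomes_k.n_svr - outcomes_0.n_svr
    dc, ds = float(delta_cost.mean()), float(delta_svr.mean())
    defined = ds > 0
    return IcerResult(
        scenario_id=outcomes_k.scenario_id,
        delta_cost_mean=dc,
        delta_svr_mean=ds,
        icer=dc / ds if defined else float("nan"),
        defined=defined,
        delta_cost=delta_cost,
        delta_svr=delta_svr,
    )


def summary_frame(outcomes: Sequence[ScenarioOutcomes], rounding: float = 100.0) -> pd.DataFrame:
    """One summary row per scenario: cost, % SVR, expenditure/SVR, BIA, ICER."""
    from .model import round_to_granularity

    base = next(o for o in outcomes if o.scenario_id == 0)
    rows = []
    for o in sorted(outcomes, key=lambda o: o.scenario_id):
        pct = pct_svr_summary(o)
        eps = expenditure_per_svr(o)
        row = {
            "scenario": o.scenario_id,
            "mean_total_cost": float(o.total_cost.mean()),
            "mean_total_cost_rounded": round_to_granularity(float(o.total_cost.mean()), rounding),
            "mean_pct_svr": pct.mean,
            "min_pct_svr": pct.min,
            "max_pct_svr": pct.max,
            "mean_n_svr": float(o.n_svr.mean()),
            "mean_expenditure_per_svr": eps.mean,
            "mean_expenditure_per_svr_rounded": round_to_granularity(eps.mean, rounding),
        }
        if o.scenario_id != 0:
            bia = budget_impact(o, base)
            ic = icer(o, base)
            row.update(
                {
                    "mean_delta_cost": bia.delta_cost.mean,
                    "pct_cost_increase": bia.pct_increase,
                    "icer": ic.icer,
                }
            )
        else:
            row.update({"mean_delta_cost": 0.0, "pct_cost_increase": 0.0, "icer": float("nan")})
        rows.append(row)
    return pd.DataFrame(rows)


def runs_frame(outcomes: Sequence[ScenarioOutcomes]) -> pd.DataFrame:
    """Tidy run-level table (one row per scenario x run)."""
    frames = []
    for o in outcomes:
        frames.append(
            pd.DataFrame(
                {
                    "scenario": o.scenario_id,
                    "run": np.arange(o.n_runs),
                    "total_cost": o.total_cost,
                    "n_treated": o.n_treated,
                    "n_svr": o.n_svr,
                    "pct_svr": o.pct_svr,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
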