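"""Monte Carlo engine for cost per SVR and savings per SVR.

Cost-effectiveness is measured as the direct cost of a full treatment
course divided by the probability of sustained virological response:

    cost per SVR = course cost / SVR probability

Published SVR rates are intervals; each simulation run draws an SVR
uniformly over the interval (maximum-entropy choice on a bounded range; the
sampler is pluggable via the ``svr_sampler`` argument).  Response-guided
protocols with two printed course costs draw one of the two variants
(fair split by default).  Savings per SVR of the new entrant against a
rival is the per-run difference

    savings = rival cost per SVR - new entrant cost per SVR

computed on common random numbers: each (therapy, subgroup) cell owns a
deterministic random stream derived from the master seed, so the same cell
always sees the same draws and summaries are bit-reproducible.

A closed form exists whenever the SVR interval stays away from zero: for
cost C ~ the variant mixture and SVR ~ U(a, b) independently,
E[C/SVR] = E[C] * ln(b/a)/(b-a)  (E[C]/a when a == b).  It serves as an
independent oracle for the sampler, never as the implementation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from math import log
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnalysisConfig,
    DistributionSummary,
    InputError,
    RegimenEntry,
    Subgroup,
    SvrRange,
    TherapyProfile,
    round_to_granularity,
)

__all__ = [
    "EligibilityError",
    "EmptySummaryError",
    "OracleUnavailableError",
    "CECell",
    "SavingsCell",
    "derived_rng",
    "sample_svr",
    "sample_course_cost",
    "cost_per_svr",
    "mc_cost_per_svr",
    "analytic_mean_cost_per_svr",
    "analytic_cost_per_svr_bounds",
    "savings_per_svr",
    "ce_table",
    "savings_table",
    "ce_table_frame",
    "savings_table_frame",
]


class EligibilityError(InputError):
    """A sampler was asked for a therapy that is not an admissible comparator."""


class EmptySummaryError(ValueError):
    """Every draw was excluded; no finite summary exists."""


class OracleUnavailableError(ValueError):
    """No closed-form mean exists (SVR interval touches zero)."""


def derived_rng(master_seed: int, *key: object) -> np.random.Generator:
    """A named, deterministic child stream of the master seed.

    The stream depends only on ``master_seed`` and the key strings, not on
    the order in which streams are created, so adding analyses never
    perturbs existing draws.
    """
    digest = hashlib.sha256("\x1f".join(str(k) for k in key).encode()).digest()
    words = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    seq = np.random.SeedSequence(int(master_seed), spawn_key=words)
    return np.random.default_rng(seq)


def sample_svr(
    svr: SvrRange,
    rng: np.random.Generator,
    size: int | None = None,
    sampler: Callable[[float, float, np.random.Generator, int | None], np.ndarray] | None = None,
):
    """Draw SVR probabilities from the interval (uniform by default).

    Degenerate intervals return the point value without consuming draws.
    """
    if svr.is_point:
        return svr.low if size is None else np.full(size, svr.low)
    if sampler is not None:
        return sampler(svr.low, svr.high, rng, size)
    return rng.uniform(svr.low, svr.high, size=size)


def sample_course_cost(
    entry: RegimenEntry,
    rng: np.random.Generator,
    size: int | None = None,
    first_variant_prob: float = 0.5,
):
    """Draw a full-course cost: the single printed cost, or one of the two
    response-guided variants (first variant with ``first_variant_prob``)."""
    if not entry.eligible:
        raise EligibilityError(
            f"therapy {entry.therapy_name!r} is not an eligible comparator here"
        )
    costs = entry.course_costs
    if len(costs) == 1:
        return costs[0] if size is None else np.full(size, costs[0])
    pick_first = rng.random(size=size) < first_variant_prob
    if size is None:
        return costs[0] if pick_first else costs[1]
    return np.where(pick_first, costs[0], costs[1])


def cost_per_svr(cost, svr):
    """Direct course cost divided by SVR probability (element-wise)."""
    cost = np.asarray(cost, dtype=float)
    svr = np.asarray(svr, dtype=float)
    if np.any(svr <= 0):
        raise ZeroDivisionError("cost per SVR is undefined at SVR = 0")
    out = cost / svr
    return float(out) if out.ndim == 0 else out


def _summarize(values: np.ndarray, n_excluded: int = 0) -> DistributionSummary:
    if values.size == 0:
        raise EmptySummaryError("all draws excluded; no finite cost per SVR")
    return DistributionSummary(
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        sd=float(values.std()),
        n_runs=int(values.size) + int(n_excluded),
        n_excluded=int(n_excluded),
    )


def _cell_draws(
    entry: RegimenEntry,
    config: AnalysisConfig,
    group: Subgroup | None,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (SVR, cost) draw vectors for one (therapy, subgroup) cell.

    When no explicit generator is given, per-cell child streams of the
    master seed are used, which is what makes draws common across every
    analysis that touches the same cell.
    """
    if not entry.eligible:
        raise EligibilityError(
            f"therapy {entry.therapy_name!r} is not an eligible comparator"
            + (f" for subgroup {group.label}" if group is not None else "")
        )
    label = group.label if group is not None else "-"
    if rng is None:
        svr_rng = derived_rng(config.master_seed, "svr", entry.therapy_name, label)
        cost_rng = derived_rng(config.master_seed, "cost", entry.therapy_name, label)
    else:
        svr_rng = cost_rng = rng
    svrs = sample_svr(entry.svr, svr_rng, size=config.n_runs)
    costs = sample_course_cost(
        entry, cost_rng, size=config.n_runs, first_variant_prob=config.cost_variant_prob
    )
    return np.asarray(svrs, dtype=float), np.asarray(costs, dtype=float)


def mc_cost_per_svr(
    entry: RegimenEntry,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
    group: Subgroup | None = None,
) -> DistributionSummary:
    """Monte Carlo summary of cost per SVR for one cell.

    Runs with a zero SVR draw (possible only when the interval is the
    degenerate [0, 0]) have no finite cost per SVR; they are excluded and
    counted in ``n_excluded``.  A point SVR with a single course cost is
    fully deterministic and collapses to the exact ratio (sd exactly 0).
    """
    if entry.eligible and entry.svr.is_point and len(entry.course_costs) == 1:
        if entry.svr.low == 0:
            raise EmptySummaryError("all draws excluded; no finite cost per SVR")
        ratio = entry.course_costs[0] / entry.svr.low
        return DistributionSummary(
            mean=ratio, min=ratio, max=ratio, sd=0.0, n_runs=config.n_runs
        )
    svrs, costs = _cell_draws(entry, config, group, rng)
    finite = svrs > 0
    return _summarize(costs[finite] / svrs[finite], n_excluded=int((~finite).sum()))


def analytic_mean_cost_per_svr(
    entry: RegimenEntry, first_variant_prob: float = 0.5
) -> float:
    """Closed-form E[cost/SVR] under the sampling model (independent oracle).

    E[1/SVR] = ln(high/low) / (high - low) for a non-degenerate uniform
    interval, 1/low for a point estimate; E[cost] is the variant mixture
    mean.  Unavailable when the interval reaches zero.
    """
    svr = entry.svr
    if svr is None or svr.low <= 0:
        raise OracleUnavailableError(
            f"therapy {entry.therapy_name!r}: no closed form when the SVR "
            f"interval touches zero"
        )
    costs = entry.course_costs
    if len(costs) == 1:
        e_cost = costs[0]
    else:
        e_cost = first_variant_prob * costs[0] + (1 - first_variant_prob) * costs[1]
    e_inv = 1.0 / svr.low if svr.is_point else log(svr.high / svr.low) / svr.width
    return e_cost * e_inv


def analytic_cost_per_svr_bounds(entry: RegimenEntry) -> tuple[float, float]:
    """Analytic support bounds (min cost / max SVR, max cost / min SVR).

    Cross-check utility: empirical Monte Carlo extremes must lie inside.
    The upper bound is infinite when the SVR interval reaches zero.
    """
    svr = entry.svr
    lo = min(entry.course_costs) / svr.high
    hi = max(entry.course_costs) / svr.low if svr.low > 0 else float("inf")
    return lo, hi


@dataclass(frozen=True)
class CECell:
    """Cost per SVR of one eligible (therapy, subgroup) cell."""

    therapy_name: str
    subgroup: Subgroup
    cost_per_svr: DistributionSummary


@dataclass(frozen=True)
class SavingsCell:
    """Savings per SVR of the new entrant vs one rival in one subgroup.

    Positive values mean the new entrant is expected to be cheaper per
    successfully treated patient than the rival.
    """

    rival_name: str
    subgroup: Subgroup
    savings: DistributionSummary
    new_entrant_name: str = ""


def savings_per_svr(
    new_entrant: RegimenEntry,
    rival: RegimenEntry,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
    group: Subgroup | None = None,
    paired: bool = True,
) -> SavingsCell:
    """Per-run (rival cost/SVR - new entrant cost/SVR), summarised.

    With ``paired=True`` (default) both cells use their own per-cell common
    random number streams, so run i of the savings series subtracts the same
    draws that produced run i of each cell's own cost-per-SVR series.
    """
    if rng is not None and paired:
        # One explicit stream cannot give both cells their own reproducible
        # draws; interleave deterministically instead.
        new_svr, new_cost = _cell_draws(new_entrant, config, group, rng)
        riv_svr, riv_cost = _cell_draws(rival, config, group, rng)
    else:
        new_svr, new_cost = _cell_draws(new_entrant, config, group, None if paired else rng)
        riv_svr, riv_cost = _cell_draws(rival, config, group, None if paired else rng)
    finite = (new_svr > 0) & (riv_svr > 0)
    diffs = riv_cost[finite] / riv_svr[finite] - new_cost[finite] / new_svr[finite]
    return SavingsCell(
        rival_name=rival.therapy_name,
        subgroup=group if group is not None else Subgroup("naive", "GT1a", "none"),
        savings=_summarize(diffs, n_excluded=int((~finite).sum())),
        new_entrant_name=new_entrant.therapy_name,
    )


def ce_table(
    therapies: Sequence[TherapyProfile],
    config: AnalysisConfig,
    groups: Iterable[Subgroup] | None = None,
) -> list[CECell]:
    """Monte Carlo cost per SVR for every eligible (therapy, subgroup) cell."""
    groups = tuple(groups) if groups is not None else Subgroup.lattice()
    cells = []
    for therapy in therapies:
        for group in groups:
            if not therapy.is_eligible(group):
                continue
            summary = mc_cost_per_svr(therapy.entry(group), config, group=group)
            cells.append(CECell(therapy.name, group, summary))
    return cells


def savings_table(
    therapies: Sequence[TherapyProfile],
    config: AnalysisConfig,
    groups: Iterable[Subgroup] | None = None,
) -> list[SavingsCell]:
    """Savings per SVR of the new entrant vs every eligible rival cell."""
    entrant = next(t for t in therapies if t.is_new_entrant)
    groups = tuple(groups) if groups is not None else Subgroup.lattice()
    cells = []
    for rival in therapies:
        if rival.is_new_entrant:
            continue
        for group in groups:
            if not (rival.is_eligible(group) and entrant.is_eligible(group)):
                continue
            cells.append(
                savings_per_svr(
                    entrant.entry(group), rival.entry(group), config, group=group
                )
            )
    return cells


def _summary_columns(summary: DistributionSummary, rounding: float) -> dict:
    return {
        "mean": summary.mean,
        "min": summary.min,
        "max": summary.max,
        "sd": summary.sd,
        "mean_rounded": round_to_granularity(summary.mean, rounding),
        "n_runs": summary.n_runs,
        "n_excluded": summary.n_excluded,
    }


def ce_table_frame(cells: Sequence[CECell], rounding: float = 100.0) -> pd.DataFrame:
    """Tidy cost-per-SVR table (one row per therapy x subgroup)."""
    rows = [
        {
            "therapy": c.therapy_name,
            "history": c.subgroup.history,
            "subtype": c.subgroup.subtype,
            "cirrhosis": c.subgroup.cirrhosis,
            **_summary_columns(c.cost_per_svr, rounding),
        }
        for c in cells
    ]
    return pd.DataFrame(rows)


def savings_table_frame(cells: Sequence[SavingsCell], rounding: float = 100.0) -> pd.DataFrame:
    """Tidy savings-per-SVR table (one row per rival x subgroup)."""
    rows = [
        {
            "rival": c.rival_name,
            "history": c.subgroup.history,
            "subtype": c.subgroup.subtype,
            "cirrhosis": c.subgroup.cirrhosis,
            **_summary_columns(c.savings, rounding),
        }
        for c in cells
    ]
    return pd.DataFrame(rows)
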