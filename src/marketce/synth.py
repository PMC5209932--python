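"""Synthetic input generation for pipeline testing.

Emulates the statistical structure the analysis assumes - per-cell uniform
SVR intervals, one- or two-variant course costs, a subgroup lattice and
product-form composition proportions - without imitating any real
epidemiology.  Three dominance modes steer where the new entrant sits
relative to its rivals:

* ``random``        - all therapies drawn freely;
* ``new_dominates`` - per cell, the new entrant's SVR interval lies
  strictly above every rival's and its cost at or below the cheapest
  rival's, which forces savings > 0 in every run (tier 1 everywhere);
* ``new_dominated`` - the reverse: the new entrant loses money per SVR in
  every run (never tier 1 or 2).

Generated SVR intervals keep a floor of 0.01 by default so the closed-form
cost-per-SVR oracle always exists; ``allow_zero_floor`` lifts that to
exercise the excluded-draw path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    EXPERIENCED_HISTORIES,
    CIRRHOSIS_STATES,
    SUBTYPES,
    PopulationSpec,
    RegimenEntry,
    Subgroup,
    SvrRange,
    TherapyProfile,
    validate_inputs,
)

__all__ = ["GenerationError", "SynthSpec", "generate_inputs", "generate_degenerate_inputs"]

SVR_FLOOR = 0.01

# How many experienced cells stay active, factored over the three axes
# (histories x subtypes x cirrhosis states).
_AXIS_FACTORS = {
    1: (1, 1, 1), 2: (1, 2, 1), 3: (3, 1, 1), 4: (1, 2, 2),
    6: (3, 2, 1), 12: (3, 2, 2),
}


class GenerationError(ValueError):
    """The requested synthetic inputs are infeasible; the message says why."""


@dataclass(frozen=True)
class SynthSpec:
    """Shape of a synthetic input set."""

    n_rivals: int = 3
    n_subgroups: int = 12
    svr_width_range: tuple[float, float] = (0.02, 0.15)
    cost_range: tuple[float, float] = (5_000.0, 60_000.0)
    dominance_mode: str = "random"
    seed: int = 0
    two_variant_prob: float = 0.5
    allow_zero_floor: bool = False

    def __post_init__(self) -> None:
        if self.n_rivals < 1:
            raise GenerationError("need at least one rival therapy")
        if self.n_subgroups not in _AXIS_FACTORS:
            raise GenerationError(
                f"n_subgroups must factor over the lattice axes "
                f"({sorted(_AXIS_FACTORS)}), got {self.n_subgroups}"
            )
        lo, hi = self.svr_width_range
        if not (0 < lo <= hi < 1):
            raise GenerationError(f"svr widths must lie in (0, 1), got {self.svr_width_range}")
        lo, hi = self.cost_range
        if not (0 < lo <= hi):
            raise GenerationError(f"cost range must be positive, got {self.cost_range}")
        if self.dominance_mode not in ("random", "new_dominates", "new_dominated"):
            raise GenerationError(f"unknown dominance mode {self.dominance_mode!r}")


def _active_groups(n_subgroups: int) -> tuple[Subgroup, ...]:
    n_h, n_s, n_c = _AXIS_FACTORS[n_subgroups]
    return tuple(
        Subgroup(h, s, c)
        for h in EXPERIENCED_HISTORIES[:n_h]
        for s in SUBTYPES[:n_s]
        for c in CIRRHOSIS_STATES[:n_c]
    )


def _axis_props(categories, n_active: int, rng: np.random.Generator) -> dict[str, float]:
    raw = rng.dirichlet(np.full(n_active, 2.0))
    props = {c: 0.0 for c in categories}
    for c, p in zip(categories[:n_active], raw):
        props[c] = float(p)
    # Renormalise exactly so sums pass strict validation.
    total = sum(props.values())
    return {c: p / total for c, p in props.items()}


def _draw_interval(rng, low_bound, high_bound, width_range) -> SvrRange:
    w_lo, w_hi = width_range
    span = high_bound - low_bound
    if span <= 0:
        raise GenerationError(
            f"cannot place an SVR interval inside [{low_bound}, {high_bound}]"
        )
    width = float(rng.uniform(w_lo, min(w_hi, span)))
    width = min(width, span)
    low = float(rng.uniform(low_bound, high_bound - width))
    return SvrRange(low, low + width)


def _draw_costs(rng, lo, hi, two_variant_prob) -> tuple[tuple[float, ...], tuple[float, ...]]:
    base = float(rng.uniform(lo, hi))
    if rng.random() < two_variant_prob:
        second = float(base * rng.uniform(1.1, 1.5))
        return (base, second), (24.0, 48.0)
    return (base,), (24.0,)


def generate_inputs(spec: SynthSpec) -> tuple[tuple[TherapyProfile, ...], PopulationSpec]:
    """Generate a validated synthetic input set (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    groups = _active_groups(spec.n_subgroups)
    floor = 0.0 if spec.allow_zero_floor else SVR_FLOOR
    rival_names = [f"rival_{i + 1:02d}" for i in range(spec.n_rivals)]

    # Rival SVR ceilings/floors leave room for a strictly dominating or
    # strictly dominated new entrant.
    margin = 2 * spec.svr_width_range[1] + 0.02
    if margin >= 0.98 - floor:
        raise GenerationError(
            f"svr_width_range {spec.svr_width_range} leaves no room for strict "
            f"dominance on [{floor}, 1]"
        )
    if spec.dominance_mode == "new_dominates":
        rival_band = (floor, 0.98 - margin)
    elif spec.dominance_mode == "new_dominated":
        rival_band = (floor + margin, 0.98)
    else:
        rival_band = (floor, 0.98)

    rival_entries: dict[str, dict[Subgroup, RegimenEntry]] = {n: {} for n in rival_names}
    new_entries: dict[Subgroup, RegimenEntry] = {}
    for group in groups:
        cell_svrs, cell_costs = [], []
        for name in rival_names:
            svr = _draw_interval(rng, rival_band[0], rival_band[1], spec.svr_width_range)
            costs, weeks = _draw_costs(rng, *spec.cost_range, spec.two_variant_prob)
            rival_entries[name][group] = RegimenEntry(
                therapy_name=name, course_costs=costs, durations=weeks, svr=svr
            )
            cell_svrs.append(svr)
            cell_costs.extend(costs)
        if spec.dominance_mode == "new_dominates":
            lo_bound = max(s.high for s in cell_svrs) + 0.005
            svr = _draw_interval(rng, lo_bound, 0.999, spec.svr_width_range)
            cost = float(min(cell_costs) * rng.uniform(0.6, 1.0))
        elif spec.dominance_mode == "new_dominated":
            hi_bound = min(s.low for s in cell_svrs) - 0.005
            svr = _draw_interval(rng, floor, hi_bound, spec.svr_width_range)
            cost = float(max(cell_costs) * rng.uniform(1.0, 1.5))
        else:
            svr = _draw_interval(rng, rival_band[0], rival_band[1], spec.svr_width_range)
            cost = float(rng.uniform(*spec.cost_range))
        new_entries[group] = RegimenEntry(
            therapy_name="new_entrant", course_costs=(cost,), durations=(12.0,), svr=svr
        )

    therapies = tuple(
        [TherapyProfile(name=n, entries=rival_entries[n]) for n in rival_names]
        + [TherapyProfile(name="new_entrant", entries=new_entries, is_new_entrant=True)]
    )

    n_h, n_s, n_c = _AXIS_FACTORS[spec.n_subgroups]
    lo = int(rng.integers(30, 120))
    population = PopulationSpec(
        total_range=(lo, lo + int(rng.integers(0, 31))),
        subtype_props=_axis_props(SUBTYPES, n_s, rng),
        history_props=_axis_props(EXPERIENCED_HISTORIES, n_h, rng),
        cirrhosis_prop=float(rng.uniform(0.1, 0.5)) if n_c == 2 else 0.0,
    )
    validate_inputs(therapies, population)
    return therapies, population


def generate_degenerate_inputs(
    seed: int = 0, n_rivals: int = 2
) -> tuple[tuple[TherapyProfile, ...], PopulationSpec]:
    """Inputs on which every downstream quantity has a closed form.

    All SVR ranges are points, all costs single-variant, and the whole
    population sits in one experienced cell with a fixed annual total, so
    expectation-mode pipeline results are exact hand computations.
    """
    rng = np.random.default_rng(seed)
    groups = _active_groups(1)
    rival_names = [f"rival_{i + 1:02d}" for i in range(n_rivals)]
    therapies = []
    for name in rival_names:
        entries = {
            g: RegimenEntry(
                therapy_name=name,
                course_costs=(float(rng.integers(80, 400) * 100),),
                durations=(24.0,),
                svr=SvrRange(*(float(rng.integers(30, 90)) / 100,) * 2),
            )
            for g in groups
        }
        therapies.append(TherapyProfile(name=name, entries=entries))
    entries = {
        g: RegimenEntry(
            therapy_name="new_entrant",
            course_costs=(float(rng.integers(300, 600) * 100),),
            durations=(12.0,),
            svr=SvrRange(*(float(rng.integers(90, 101)) / 100,) * 2),
        )
        for g in groups
    }
    therapies.append(TherapyProfile(name="new_entrant", entries=entries, is_new_entrant=True))
    population = PopulationSpec(
        total_range=(60, 60),
        subtype_props={"GT1a": 1.0, "GT1b": 0.0},
        history_props={"relapser": 1.0, "partial_responder": 0.0, "null_responder": 0.0},
        cirrhosis_prop=0.0,
    )
    therapies = tuple(therapies)
    validate_inputs(therapies, population)
    return therapies, population
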