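"""Domain types for the market-entry cost-effectiveness model.

The unit of analysis is a *subgroup lattice* of chronic HCV genotype-1
patients: treatment history (naive, relapser, partial responder, null
responder) x GT1 subtype (1a, 1b) x cirrhosis status (none, compensated),
16 cells in all, of which the 12 non-naive cells form the "experienced"
population that budget-impact scenarios act on.

Each therapy is described per cell by a :class:`RegimenEntry`: one or two
full-course costs (two where the protocol is response-guided and the short
and long course are both possible), the matching durations in weeks, and a
sustained-virological-response (SVR) probability range.  Effectiveness is
measured solely as SVR; "cost per SVR" (course cost divided by SVR
probability) is the model's unit of cost-effectiveness.

All monetary amounts are euros per full course, VAT included, stored
unrounded; rounding to the reporting granularity (default EUR 100) happens
only when tables are written.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

__all__ = [
    "HISTORIES",
    "EXPERIENCED_HISTORIES",
    "SUBTYPES",
    "CIRRHOSIS_STATES",
    "InputError",
    "ValidationError",
    "SvrRange",
    "Subgroup",
    "RegimenEntry",
    "TherapyProfile",
    "PopulationSpec",
    "AnalysisConfig",
    "DistributionSummary",
    "round_to_granularity",
    "validate_inputs",
]

HISTORIES = ("naive", "relapser", "partial_responder", "null_responder")
EXPERIENCED_HISTORIES = ("relapser", "partial_responder", "null_responder")
SUBTYPES = ("GT1a", "GT1b")
CIRRHOSIS_STATES = ("none", "compensated")

_PROP_TOL = 1e-9


class InputError(ValueError):
    """Malformed input file or record."""


class ValidationError(InputError):
    """A domain invariant is violated; the message names the offending cell."""


def round_to_granularity(value: float, granularity: float = 100.0) -> float:
    """Round a monetary amount to the reporting granularity (default EUR 100)."""
    if granularity <= 0:
        return value
    return round(value / granularity) * granularity


@dataclass(frozen=True)
class SvrRange:
    """An interval of SVR probabilities (fractions in [0, 1]).

    Degenerate ranges (``low == high``) are valid point estimates, e.g. a
    single trial value for the new entrant.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValidationError(
                f"SVR range must satisfy 0 <= low <= high <= 1, got "
                f"[{self.low}, {self.high}]"
            )

    @property
    def is_point(self) -> bool:
        return self.low == self.high

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class Subgroup:
    """One cell of the patient lattice: history x subtype x cirrhosis."""

    history: str
    subtype: str
    cirrhosis: str

    def __post_init__(self) -> None:
        if self.history not in HISTORIES:
            raise ValidationError(f"unknown treatment history {self.history!r}")
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown GT1 subtype {self.subtype!r}")
        if self.cirrhosis not in CIRRHOSIS_STATES:
            raise ValidationError(f"unknown cirrhosis state {self.cirrhosis!r}")

    @property
    def is_experienced(self) -> bool:
        return self.history != "naive"

    @property
    def label(self) -> str:
        return f"{self.history}/{self.subtype}/{self.cirrhosis}"

    @property
    def sort_index(self) -> tuple[int, int, int]:
        return (
            HISTORIES.index(self.history),
            SUBTYPES.index(self.subtype),
            CIRRHOSIS_STATES.index(self.cirrhosis),
        )

    @classmethod
    def lattice(cls) -> tuple["Subgroup", ...]:
        """The full 4 x 2 x 2 = 16-cell lattice, in canonical order."""
        return tuple(
            cls(h, s, c)
            for h in HISTORIES
            for s in SUBTYPES
            for c in CIRRHOSIS_STATES
        )

    @classmethod
    def experienced(cls) -> tuple["Subgroup", ...]:
        """The 12 experienced (non-naive) cells, in canonical order."""
        return tuple(g for g in cls.lattice() if g.is_experienced)


@dataclass(frozen=True)
class RegimenEntry:
    """Costs, durations and SVR range for one therapy in one subgroup.

    ``course_costs`` holds one or two full-course amounts; two entries encode
    a response-guided protocol whose short and long course differ in price.
    ``durations`` is positionally paired with ``course_costs``.  Ineligible
    entries (``eligible=False``) mark therapies that are not an admissible
    comparator for the subgroup and carry no cost/SVR requirements.
    """

    therapy_name: str
    course_costs: tuple[float, ...] = ()
    durations: tuple[float, ...] = ()
    svr: SvrRange | None = None
    eligible: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "course_costs", tuple(self.course_costs))
        object.__setattr__(self, "durations", tuple(self.durations))
        if not self.eligible:
            return
        where = f"therapy {self.therapy_name!r}"
        if not self.course_costs:
            raise ValidationError(f"{where}: eligible entry needs >= 1 course cost")
        if len(self.course_costs) > 2:
            raise ValidationError(f"{where}: at most 2 course-cost variants allowed")
        if any(c <= 0 for c in self.course_costs):
            raise ValidationError(f"{where}: course costs must be positive")
        if len(self.durations) != len(self.course_costs):
            raise ValidationError(
                f"{where}: durations must pair with course costs "
                f"({len(self.durations)} vs {len(self.course_costs)})"
            )
        if any(d <= 0 for d in self.durations):
            raise ValidationError(f"{where}: durations must be positive")
        if self.svr is None:
            raise ValidationError(f"{where}: eligible entry needs an SVR range")

    @property
    def mean_course_cost(self) -> float:
        return sum(self.course_costs) / len(self.course_costs)


@dataclass(frozen=True)
class TherapyProfile:
    """One therapy across the subgroup lattice."""

    name: str
    entries: Mapping[Subgroup, RegimenEntry] = field(default_factory=dict)
    is_new_entrant: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for group, entry in self.entries.items():
            if entry.therapy_name != self.name:
                raise ValidationError(
                    f"therapy {self.name!r}, subgroup {group.label}: entry is "
                    f"labelled {entry.therapy_name!r}"
                )

    def entry(self, group: Subgroup) -> RegimenEntry:
        return self.entries[group]

    def is_eligible(self, group: Subgroup) -> bool:
        entry = self.entries.get(group)
        return entry is not None and entry.eligible

    def eligible_subgroups(self) -> Iterator[Subgroup]:
        for group in sorted(self.entries, key=lambda g: g.sort_index):
            if self.entries[group].eligible:
                yield group


def _check_props(props: Mapping[str, float], allowed: tuple[str, ...], what: str) -> None:
    unknown = set(props) - set(allowed)
    if unknown:
        raise ValidationError(f"{what}: unknown categories {sorted(unknown)}")
    if any(p < 0 for p in props.values()):
        raise ValidationError(f"{what}: proportions must be non-negative")
    total = sum(props.values())
    if abs(total - 1.0) > _PROP_TOL:
        raise ValidationError(f"{what}: proportions sum to {total}, expected 1")


@dataclass(frozen=True)
class PopulationSpec:
    """Annual eligible population and its composition over the lattice.

    The composition is assumed independent across the three axes, so the
    probability of an experienced cell is
    ``history_props[h] * subtype_props[s] * (cirrhosis_prop or its complement)``.
    Naive patients can appear in cost-effectiveness tables but are excluded
    from budget-impact scenarios (``include_naive`` defaults to False).
    """

    total_range: tuple[int, int]
    subtype_props: Mapping[str, float]
    history_props: Mapping[str, float]
    cirrhosis_prop: float
    include_naive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_range", tuple(int(v) for v in self.total_range))
        object.__setattr__(self, "subtype_props", dict(self.subtype_props))
        object.__setattr__(self, "history_props", dict(self.history_props))
        lo, hi = self.total_range
        if not (0 < lo <= hi):
            raise ValidationError(
                f"population total_range must be positive with low <= high, got [{lo}, {hi}]"
            )
        _check_props(self.subtype_props, SUBTYPES, "PopulationSpec.subtype_props")
        _check_props(
            self.history_props, EXPERIENCED_HISTORIES, "PopulationSpec.history_props"
        )
        if not (0.0 <= self.cirrhosis_prop <= 1.0):
            raise ValidationError(
                f"PopulationSpec.cirrhosis_prop must lie in [0, 1], got {self.cirrhosis_prop}"
            )

    def cell_probabilities(self) -> dict[Subgroup, float]:
        """Probability of each experienced cell under the independence assumption."""
        probs: dict[Subgroup, float] = {}
        for group in Subgroup.experienced():
            p_c = self.cirrhosis_prop if group.cirrhosis == "compensated" else 1.0 - self.cirrhosis_prop
            probs[group] = (
                self.history_props[group.history]
                * self.subtype_props[group.subtype]
                * p_c
            )
        return probs


@dataclass(frozen=True)
class AnalysisConfig:
    """Simulation settings.

    tier3_threshold is the takeover boundary for the third market-entry
    scenario: the new entrant additionally claims cells where it is up to
    this much more expensive per SVR on average (EUR 10 000 by default).
    cost_variant_prob is the probability of the *first* listed course-cost
    variant when a protocol is response-guided (fair split by default).
    """

    n_runs: int = 10_000
    master_seed: int = 20_150
    tier3_threshold: float = 10_000.0
    baseline_strategy: str = "cheapest_per_svr"
    reporting_rounding: float = 100.0
    cost_variant_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValidationError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.tier3_threshold < 0:
            raise ValidationError(
                f"tier3_threshold must be >= 0, got {self.tier3_threshold}"
            )
        if self.baseline_strategy not in ("cheapest_per_svr", "equal_eligible"):
            raise ValidationError(
                f"unknown baseline strategy {self.baseline_strategy!r}"
            )
        if not (0.0 <= self.cost_variant_prob <= 1.0):
            raise ValidationError(
                f"cost_variant_prob must lie in [0, 1], got {self.cost_variant_prob}"
            )

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DistributionSummary:
    """Summary of a Monte Carlo distribution: mean, empirical range, sd.

    The reported min/max are empirical extremes over the simulated runs, not
    analytic bounds.  ``n_excluded`` counts draws dropped because the
    quantity was undefined (e.g. a zero SVR draw makes cost per SVR
    non-finite); excluded draws do not enter mean/min/max/sd.
    """

    mean: float
    min: float
    max: float
    sd: float
    n_runs: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValidationError("DistributionSummary needs n_runs >= 1")
        if self.n_excluded < 0 or self.n_excluded > self.n_runs:
            raise ValidationError("n_excluded must lie in [0, n_runs]")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        tol = 1e-9 * max(1.0, abs(self.mean))  # accumulation round-off
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ValidationError(
                f"summary must satisfy min <= mean <= max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )


def validate_inputs(
    therapies: tuple[TherapyProfile, ...] | list[TherapyProfile],
    population: PopulationSpec | None = None,
) -> None:
    """Validate a full input set beyond per-object invariants.

    Checks: therapy names unique; exactly one new entrant; the new entrant is
    eligible for every subgroup it covers; every experienced cell has at
    least one eligible rival (otherwise no baseline market exists).
    Raises :class:`ValidationError` naming the first offending cell.
    """
    names = [t.name for t in therapies]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate therapy names in {names}")
    entrants = [t for t in therapies if t.is_new_entrant]
    if len(entrants) != 1:
        raise ValidationError(
            f"exactly one therapy must be the new entrant, found "
            f"{[t.name for t in entrants]}"
        )
    entrant = entrants[0]
    for group, entry in entrant.entries.items():
        if not entry.eligible:
            raise ValidationError(
                f"new entrant {entrant.name!r} must be eligible in every covered "
                f"subgroup; ineligible in {group.label}"
            )
    rivals = [t for t in therapies if not t.is_new_entrant]
    for group in Subgroup.experienced():
        if group in entrant.entries and not any(r.is_eligible(group) for r in rivals):
            raise ValidationError(
                f"subgroup {group.label}: no eligible rival therapy"
            )
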