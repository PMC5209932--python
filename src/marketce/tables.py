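"""Built-in input set: the Croatian HCV GT1 market, 2015.

Encodes the published SVR ranges, therapy durations and full-course direct
costs (EUR 2015, VAT included, CHIF price list; ribavirin donated and
therefore costless) for the five regimens competing for GT1 patients at the
time the interferon-free OBV/PTV/r/DSV combination entered the market:

* OBV/PTV/r/DSV (ombitasvir/paritaprevir/ritonavir + dasabuvir) - the new
  entrant; point SVR estimates from its registration trials,
* pegIFN        - dual pegylated-interferon/ribavirin, standard of care for
  naive patients only (not recommended for experienced GT1 patients, hence
  marked ineligible for all experienced cells),
* BOC+pegIFN, TPV+pegIFN, SIM+pegIFN - first-wave protease-inhibitor triple
  therapies, the rival comparators.

Two-valued cost/duration cells (e.g. "24/48" weeks, "23 200/32 700" EUR)
are response-guided protocols: the short and the long course are both
possible and are sampled as discrete variants.

Population: 90-100 treatment-experienced GT1 patients per year; subtype
64% 1b and 36% 1a (the published 22% 1a plus 14% mixed/unknown, which the
source analysis folds into 1a).  The history split (relapser 0.40, partial
responder 0.30, null responder 0.30) and compensated-cirrhosis share (0.30)
are NOT published figures: they are this package's documented default
assumptions, kept configurable, and every scenario-level result depends on
them.
"""

from __future__ import annotations

from .model import (
    AnalysisConfig,
    PopulationSpec,
    RegimenEntry,
    Subgroup,
    SvrRange,
    TherapyProfile,
)

__all__ = ["croatia_gt1_inputs", "NEW_ENTRANT", "RIVALS"]

NEW_ENTRANT = "OBV/PTV/r/DSV"
RIVALS = ("pegIFN", "BOC+pegIFN", "TPV+pegIFN", "SIM+pegIFN")

# Per therapy: {(history, cirrhosis): (costs, weeks, {subtype: (svr_lo, svr_hi)})}
# SVR values are percentages as published; converted to fractions on build.
_A, _B = "GT1a", "GT1b"
_BOTH = (_A, _B)


def _cell(costs, weeks, svr_by_subtype):
    return (costs, weeks, svr_by_subtype)


_OBV = {
    ("naive", "none"): _cell((45_000,), (12,), {_A: (95.9, 95.9), _B: (100, 100)}),
    ("naive", "compensated"): {
        _A: _cell((90_000,), (24,), {_A: (94.6, 94.6)}),
        _B: _cell((45_000,), (12,), {_B: (100, 100)}),
    },
    ("relapser", "none"): _cell((45_000,), (12,), {_A: (94, 94), _B: (100, 100)}),
    ("relapser", "compensated"): {
        _A: _cell((90_000,), (24,), {_A: (100, 100)}),
        _B: _cell((45_000,), (12,), {_B: (100, 100)}),
    },
    ("partial_responder", "none"): _cell((45_000,), (12,), {_A: (100, 100), _B: (100, 100)}),
    ("partial_responder", "compensated"): {
        _A: _cell((90_000,), (24,), {_A: (100, 100)}),
        _B: _cell((45_000,), (12,), {_B: (85.7, 85.7)}),
    },
    ("null_responder", "none"): _cell((45_000,), (12,), {_A: (95.4, 95.4), _B: (100, 100)}),
    ("null_responder", "compensated"): {
        _A: _cell((90_000,), (24,), {_A: (92.9, 92.9)}),
        _B: _cell((45_000,), (12,), {_B: (100, 100)}),
    },
}

_PEGIFN = {
    ("naive", "none"): _cell((4_200, 8_400), (24, 48), {s: (35, 50) for s in _BOTH}),
    ("naive", "compensated"): _cell((8_400,), (48,), {s: (33, 38) for s in _BOTH}),
    # Experienced GT1 patients are not treated with dual therapy (SVR as low
    # as 0% for partial/null response; excluded from payer guidelines).
}

_BOC = {
    ("naive", "none"): _cell((23_200, 32_700), (28, 48), {s: (52, 67) for s in _BOTH}),
    ("naive", "compensated"): _cell((41_900,), (48,), {s: (52, 55) for s in _BOTH}),
    ("relapser", "none"): _cell((32_700,), (48,), {s: (75, 93) for s in _BOTH}),
    ("relapser", "compensated"): _cell((41_900,), (48,), {s: (34, 54) for s in _BOTH}),
    ("partial_responder", "none"): _cell((32_700,), (48,), {s: (52, 67) for s in _BOTH}),
    ("partial_responder", "compensated"): _cell((41_900,), (48,), {s: (34, 38) for s in _BOTH}),
    ("null_responder", "none"): _cell((41_900,), (48,), {s: (38, 39) for s in _BOTH}),
    ("null_responder", "compensated"): _cell((41_900,), (48,), {s: (0, 34) for s in _BOTH}),
}

_TPV = {
    ("naive", "none"): _cell((30_200, 34_300), (24, 48), {s: (64, 85) for s in _BOTH}),
    ("naive", "compensated"): _cell((34_300,), (48,), {s: (53, 71) for s in _BOTH}),
    ("relapser", "none"): _cell((30_200, 34_300), (24, 48), {s: (83, 88) for s in _BOTH}),
    ("relapser", "compensated"): _cell((34_300,), (48,), {s: (74.2, 84) for s in _BOTH}),
    ("partial_responder", "none"): _cell((30_200, 34_300), (24, 48), {s: (54, 79) for s in _BOTH}),
    ("partial_responder", "compensated"): _cell((34_300,), (48,), {s: (34, 40) for s in _BOTH}),
    ("null_responder", "none"): _cell((34_300,), (48,), {s: (33, 43) for s in _BOTH}),
    ("null_responder", "compensated"): _cell((34_300,), (48,), {s: (14, 19) for s in _BOTH}),
}

_SIM = {
    ("naive", "none"): _cell((32_800,), (24,), {s: (68, 84) for s in _BOTH}),
    ("naive", "compensated"): _cell((32_800,), (24,), {s: (57, 60) for s in _BOTH}),
    ("relapser", "none"): _cell((32_800,), (24,), {s: (57, 82) for s in _BOTH}),
    ("relapser", "compensated"): _cell((32_800,), (24,), {s: (46, 74) for s in _BOTH}),
    ("partial_responder", "none"): _cell((36_900,), (48,), {s: (57, 79) for s in _BOTH}),
    ("partial_responder", "compensated"): _cell((36_900,), (48,), {s: (46, 82) for s in _BOTH}),
    ("null_responder", "none"): _cell((36_900,), (48,), {s: (33, 66) for s in _BOTH}),
    ("null_responder", "compensated"): _cell((36_900,), (48,), {s: (31, 46) for s in _BOTH}),
}

_TABLES = {
    NEW_ENTRANT: _OBV,
    "pegIFN": _PEGIFN,
    "BOC+pegIFN": _BOC,
    "TPV+pegIFN": _TPV,
    "SIM+pegIFN": _SIM,
}


def _build_profile(name: str, table: dict) -> TherapyProfile:
    entries: dict[Subgroup, RegimenEntry] = {}
    for group in Subgroup.lattice():
        key = (group.history, group.cirrhosis)
        spec = table.get(key)
        if spec is None:
            entries[group] = RegimenEntry(therapy_name=name, eligible=False)
            continue
        if isinstance(spec, dict):  # subtype-specific cost/duration (OBV cirrhotics)
            spec = spec[group.subtype]
        costs, weeks, svr_by_subtype = spec
        lo, hi = svr_by_subtype[group.subtype]
        entries[group] = RegimenEntry(
            therapy_name=name,
            course_costs=tuple(float(c) for c in costs),
            durations=tuple(float(w) for w in weeks),
            # round: percent-to-fraction conversion must hit the same double
            # the decimal literal would parse to
            svr=SvrRange(round(lo / 100.0, 12), round(hi / 100.0, 12)),
        )
    return TherapyProfile(name=name, entries=entries, is_new_entrant=name == NEW_ENTRANT)


def croatia_gt1_inputs() -> tuple[tuple[TherapyProfile, ...], PopulationSpec, AnalysisConfig]:
    """The built-in Croatian GT1 2015 input set.

    Returns the five therapy profiles over the full 16-cell lattice, the
    population specification and the default analysis configuration.
    """
    therapies = tuple(_build_profile(name, table) for name, table in _TABLES.items())
    population = PopulationSpec(
        total_range=(90, 100),
        subtype_props={"GT1a": 0.36, "GT1b": 0.64},
        history_props={
            "relapser": 0.40,
            "partial_responder": 0.30,
            "null_responder": 0.30,
        },
        cirrhosis_prop=0.30,
    )
    return therapies, population, AnalysisConfig()
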