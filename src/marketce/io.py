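"""Input/output: therapy tables, population specs, configs, result tables.

Two on-disk forms are supported:

* a YAML or JSON *bundle* holding the therapy table (one record per
  therapy x subgroup cell), the population specification and the analysis
  configuration together;
* a bare CSV therapy table (columns ``therapy, new_entrant, history,
  subtype, cirrhosis, eligible, cost_1, cost_2, weeks_1, weeks_2,
  svr_low, svr_high``), with population/config supplied separately or
  defaulted.

Result tables are tidy CSV; monetary columns gain a ``*_rounded``
companion at the configured reporting granularity while raw values are
kept at full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .model import (
    AnalysisConfig,
    InputError,
    PopulationSpec,
    RegimenEntry,
    Subgroup,
    SvrRange,
    TherapyProfile,
    ValidationError,
    round_to_granularity,
    validate_inputs,
)

__all__ = [
    "load_inputs",
    "save_inputs",
    "inputs_to_dict",
    "inputs_from_dict",
    "therapies_to_frame",
    "frame_to_therapies",
    "write_results",
    "read_results",
]

_CSV_COLUMNS = [
    "therapy", "new_entrant", "history", "subtype", "cirrhosis", "eligible",
    "cost_1", "cost_2", "weeks_1", "weeks_2", "svr_low", "svr_high",
]


def _entry_row(name: str, new_entrant: bool, group: Subgroup, entry: RegimenEntry) -> dict:
    costs = list(entry.course_costs) + [None] * (2 - len(entry.course_costs))
    weeks = list(entry.durations) + [None] * (2 - len(entry.durations))
    return {
        "therapy": name,
        "new_entrant": new_entrant,
        "history": group.history,
        "subtype": group.subtype,
        "cirrhosis": group.cirrhosis,
        "eligible": entry.eligible,
        "cost_1": costs[0],
        "cost_2": costs[1],
        "weeks_1": weeks[0],
        "weeks_2": weeks[1],
        "svr_low": entry.svr.low if entry.svr else None,
        "svr_high": entry.svr.high if entry.svr else None,
    }


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


def _row_to_entry(row: dict, where: str) -> tuple[str, bool, Subgroup, RegimenEntry]:
    try:
        group = Subgroup(str(row["history"]), str(row["subtype"]), str(row["cirrhosis"]))
        name = str(row["therapy"])
        eligible = bool(row.get("eligible", True))
        if not eligible:
            return name, bool(row.get("new_entrant", False)), group, RegimenEntry(
                therapy_name=name, eligible=False
            )
        costs = tuple(float(row[c]) for c in ("cost_1", "cost_2") if not _is_missing(row.get(c)))
        weeks = tuple(float(row[c]) for c in ("weeks_1", "weeks_2") if not _is_missing(row.get(c)))
        svr = SvrRange(float(row["svr_low"]), float(row["svr_high"]))
        entry = RegimenEntry(therapy_name=name, course_costs=costs, durations=weeks, svr=svr)
        return name, bool(row.get("new_entrant", False)), group, entry
    except KeyError as exc:
        raise InputError(f"{where}: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise ValidationError(f"{where}: {exc}") from exc
        raise InputError(f"{where}: {exc}") from exc


def therapies_to_frame(therapies: Sequence[TherapyProfile]) -> pd.DataFrame:
    rows = []
    for therapy in therapies:
        for group in sorted(therapy.entries, key=lambda g: g.sort_index):
            rows.append(_entry_row(therapy.name, therapy.is_new_entrant, group, therapy.entries[group]))
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_therapies(frame: pd.DataFrame, where: str = "therapy table") -> tuple[TherapyProfile, ...]:
    profiles: dict[str, dict] = {}
    for i, row in enumerate(frame.to_dict("records")):
        name, new_entrant, group, entry = _row_to_entry(
            row, f"{where}, record {i + 1} "
            f"(therapy={row.get('therapy')!r}, cell={row.get('history')}/"
            f"{row.get('subtype')}/{row.get('cirrhosis')})"
        )
        slot = profiles.setdefault(name, {"new_entrant": new_entrant, "entries": {}})
        slot["new_entrant"] = slot["new_entrant"] or new_entrant
        if group in slot["entries"]:
            raise InputError(f"{where}: duplicate cell {group.label} for therapy {name!r}")
        slot["entries"][group] = entry
    return tuple(
        TherapyProfile(name=name, entries=slot["entries"], is_new_entrant=slot["new_entrant"])
        for name, slot in profiles.items()
    )


def inputs_to_dict(
    therapies: Sequence[TherapyProfile],
    population: PopulationSpec,
    config: AnalysisConfig,
) -> dict:
    return {
        "therapies": therapies_to_frame(therapies).to_dict("records"),
        "population": {
            "total_range": list(population.total_range),
            "subtype_props": dict(population.subtype_props),
            "history_props": dict(population.history_props),
            "cirrhosis_prop": population.cirrhosis_prop,
            "include_naive": population.include_naive,
        },
        "config": asdict(config),
    }


def inputs_from_dict(data: dict, where: str = "input bundle"):
    if "therapies" not in data:
        raise InputError(f"{where}: missing 'therapies' section")
    therapies = frame_to_therapies(pd.DataFrame(data["therapies"]), where=where)
    pop_data = data.get("population")
    if pop_data is None:
        raise InputError(f"{where}: missing 'population' section")
    try:
        population = PopulationSpec(
            total_range=tuple(pop_data["total_range"]),
            subtype_props=pop_data["subtype_props"],
            history_props=pop_data["history_props"],
            cirrhosis_prop=float(pop_data["cirrhosis_prop"]),
            include_naive=bool(pop_data.get("include_naive", False)),
        )
    except KeyError as exc:
        raise InputError(f"{where}: population section missing field {exc}") from exc
    config = AnalysisConfig(**data.get("config", {}))
    validate_inputs(therapies, population)
    return therapies, population, config


def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("yml", "yaml"):
        return "yaml"
    if suffix in ("json", "csv"):
        return suffix
    raise InputError(f"cannot infer input format from {path.name!r}; pass format=")


def load_inputs(
    path: str | Path,
    format: str | None = None,
    population: PopulationSpec | None = None,
    config: AnalysisConfig | None = None,
):
    """Load and validate a full input set.

    YAML/JSON bundles carry therapies, population and config together.  A
    bare CSV therapy table may be combined with ``population``/``config``
    given in code (config defaults apply when omitted; a population is
    required for CSV input).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file {path} does not exist")
    fmt = _detect_format(path, format)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:
            raise InputError(f"{path.name}: cannot parse CSV: {exc}") from exc
        therapies = frame_to_therapies(frame, where=path.name)
        if population is None:
            raise InputError(
                f"{path.name}: CSV therapy tables need a population specification"
            )
        validate_inputs(therapies, population)
        return therapies, population, config or AnalysisConfig()
    text = path.read_text()
    try:
        data = yaml.safe_load(text) if fmt == "yaml" else json.loads(text)
    except yaml.YAMLError as exc:
        raise InputError(f"{path.name}: cannot parse YAML: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise InputError(
            f"{path.name}: cannot parse JSON at line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict):
        raise InputError(f"{path.name}: expected a mapping at top level")
    therapies, loaded_pop, loaded_cfg = inputs_from_dict(data, where=path.name)
    return therapies, population or loaded_pop, config or loaded_cfg


def save_inputs(
    therapies: Sequence[TherapyProfile],
    population: PopulationSpec,
    config: AnalysisConfig,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write an input set (YAML/JSON bundle, or bare CSV therapy table)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "csv":
        therapies_to_frame(therapies).to_csv(path, index=False)
        return
    data = inputs_to_dict(therapies, population, config)
    if fmt == "yaml":
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


_MONEY_HINTS = ("cost", "savings", "expenditure", "icer")


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    rounding: float = 100.0,
) -> None:
    """Write a tidy result table as CSV.

    Monetary columns (name containing cost/savings/expenditure/icer) gain a
    ``*_rounded`` companion at the reporting granularity; raw values are
    written with full precision.  An empty result set yields a header-only
    file.
    """
    frame = results.copy()
    for col in list(frame.columns):
        if col.endswith("_rounded") or not any(h in col for h in _MONEY_HINTS):
            continue
        rounded_name = f"{col}_rounded"
        if rounded_name not in frame.columns and pd.api.types.is_numeric_dtype(frame[col]):
            frame[rounded_name] = frame[col].map(
                lambda v: round_to_granularity(v, rounding) if pd.notna(v) else v
            )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
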