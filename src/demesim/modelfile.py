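"""Text model-definition files (YAML dialect).

A model file is an indented key/value mapping with the keys ``id``,
``description``, ``generation_time``, ``populations``, ``initial_sizes``,
``initial_growth_rates``, ``migration_matrix``, ``events`` and ``citations``.
Events are tagged records, e.g.::

    events:
      - {type: lineage_move, time: 4000, source: 1, dest: 0, proportion: 1.0}
      - {type: size_growth_change, time: 4000, population: 0, new_size: 7300}
      - {type: migration_change, time: 4000, source: all, dest: all, new_rate: 0}

Round trips are exact at the canonical-form level: ``load(dump(m))`` compares
equal to ``m`` under :func:`demesim.demography.models_equal`.  Events listed
out of time order are accepted and sorted stably.
"""

from __future__ import annotations

from typing import List, Optional

import yaml

from .demography import (
    ALL,
    Citation,
    DemographicModel,
    LineageMove,
    MigrationChange,
    PopulationDef,
    SizeGrowthChange,
    validate_model,
)

__all__ = ["load_model_file", "dump_model_file", "ModelFileError"]

_TOP_KEYS = {
    "id",
    "description",
    "generation_time",
    "populations",
    "initial_sizes",
    "initial_growth_rates",
    "migration_matrix",
    "events",
    "citations",
}
_REQUIRED = {"id", "populations", "initial_sizes", "migration_matrix"}

_EVENT_KEYS = {
    "size_growth_change": {"type", "time", "population", "new_size", "new_growth_rate"},
    "migration_change": {"type", "time", "source", "dest", "new_rate"},
    "lineage_move": {"type", "time", "source", "dest", "proportion"},
}


class ModelFileError(ValueError):
    """Malformed model-definition file; message carries line/key context."""


def _pop_idx(value, where: str) -> Optional[int]:
    if value is None or value == "all":
        return ALL
    if isinstance(value, bool) or not isinstance(value, int):
        raise ModelFileError(f"{where}: expected integer population index or 'all', got {value!r}")
    return value


def _num(record, key, where, default=None, required=False):
    if key not in record or record[key] is None:
        if required:
            raise ModelFileError(f"{where}: missing required key '{key}'")
        return default
    v = record[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ModelFileError(f"{where}.{key}: expected a number, got {v!r}")
    return float(v)


def _parse_event(record: dict, where: str):
    if not isinstance(record, dict):
        raise ModelFileError(f"{where}: event must be a mapping, got {record!r}")
    etype = record.get("type")
    if etype not in _EVENT_KEYS:
        raise ModelFileError(
            f"{where}: unknown event type {etype!r} "
            f"(expected one of {sorted(_EVENT_KEYS)})"
        )
    unknown = set(record) - _EVENT_KEYS[etype]
    if unknown:
        raise ModelFileError(f"{where}: unknown keys {sorted(unknown)} for {etype}")
    time = _num(record, "time", where, required=True)
    if etype == "size_growth_change":
        return SizeGrowthChange(
            time=time,
            population=_pop_idx(record.get("population"), where + ".population"),
            new_size=_num(record, "new_size", where),
            new_growth_rate=_num(record, "new_growth_rate", where),
        )
    if etype == "migration_change":
        return MigrationChange(
            time=time,
            source=_pop_idx(record.get("source"), where + ".source"),
            dest=_pop_idx(record.get("dest"), where + ".dest"),
            new_rate=_num(record, "new_rate", where, required=True),
        )
    return LineageMove(
        time=time,
        source=_pop_idx(record.get("source"), where + ".source"),
        dest=_pop_idx(record.get("dest"), where + ".dest"),
        proportion=_num(record, "proportion", where, default=1.0),
    )


def load_model_file(text: str) -> DemographicModel:
    """Parse a model-definition file and validate the resulting model.

    Raises :class:`ModelFileError` on syntax errors (with the YAML line mark),
    unknown keys, missing required fields, or a model that fails validation.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelFileError(f"model file is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelFileError("model file must be a top-level mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ModelFileError(f"unknown top-level keys: {sorted(unknown)}")
    missing = _REQUIRED - set(data)
    if missing:
        raise ModelFileError(f"missing required keys: {sorted(missing)}")

    pops: List[PopulationDef] = []
    raw_pops = data["populations"]
    if not isinstance(raw_pops, list):
        raise ModelFileError("populations: expected a list")
    for k, p in enumerate(raw_pops):
        where = f"populations[{k}]"
        if isinstance(p, str):
            pops.append(PopulationDef(id=p))
        elif isinstance(p, dict):
            unknown = set(p) - {"id", "description", "sampling_time"}
            if unknown:
                raise ModelFileError(f"{where}: unknown keys {sorted(unknown)}")
            if "id" not in p:
                raise ModelFileError(f"{where}: missing 'id'")
            pops.append(
                PopulationDef(
                    id=str(p["id"]),
                    description=str(p.get("description", "")),
                    sampling_time=_num(p, "sampling_time", where, default=0.0),
                )
            )
        else:
            raise ModelFileError(f"{where}: expected a string or mapping")

    P = len(pops)
    events = [
        _parse_event(e, f"events[{k}]") for k, e in enumerate(data.get("events") or [])
    ]
    # stable sort: out-of-order files are accepted, listed order kept per time
    events.sort(key=lambda e: e.time)

    citations = []
    for k, c in enumerate(data.get("citations") or []):
        if isinstance(c, str):
            citations.append(Citation(doi=c))
        elif isinstance(c, dict):
            citations.append(
                Citation(doi=str(c.get("doi", "")), role=str(c.get("role", "model")))
            )
        else:
            raise ModelFileError(f"citations[{k}]: expected a string or mapping")

    model = DemographicModel(
        id=str(data["id"]),
        description=str(data.get("description", "")),
        populations=pops,
        initial_sizes=[float(x) for x in data["initial_sizes"]],
        initial_growth_rates=[
            float(x) for x in data.get("initial_growth_rates") or [0.0] * P
        ],
        migration_matrix=[[float(x) for x in row] for row in data["migration_matrix"]],
        events=events,
        generation_time=_num(data, "generation_time", "<top>", default=1.0),
        citations=citations,
    )
    violations = validate_model(model)
    if violations:
        raise ModelFileError(
            "model file parsed but failed validation:\n" + "\n".join(violations)
        )
    return model


def _event_record(ev) -> dict:
    def pop(v):
        return "all" if v is ALL else v

    if isinstance(ev, SizeGrowthChange):
        rec = {"type": "size_growth_change", "time": ev.time, "population": pop(ev.population)}
        if ev.new_size is not None:
            rec["new_size"] = ev.new_size
        if ev.new_growth_rate is not None:
            rec["new_growth_rate"] = ev.new_growth_rate
        return rec
    if isinstance(ev, MigrationChange):
        return {
            "type": "migration_change",
            "time": ev.time,
            "source": pop(ev.source),
            "dest": pop(ev.dest),
            "new_rate": ev.new_rate,
        }
    return {
        "type": "lineage_move",
        "time": ev.time,
        "source": ev.source,
        "dest": ev.dest,
        "proportion": ev.proportion,
    }


def dump_model_file(model: DemographicModel) -> str:
    """Serialize a model to the model-definition dialect."""
    data = {
        "id": model.id,
        "description": model.description,
        "generation_time": model.generation_time,
        "populations": [
            {"id": p.id, "description": p.description, "sampling_time": p.sampling_time}
            for p in model.populations
        ],
        "initial_sizes": [float(x) for x in model.initial_sizes],
        "initial_growth_rates": [float(x) for x in model.initial_growth_rates],
        "migration_matrix": [[float(x) for x in row] for row in model.migration_matrix],
        "events": [_event_record(e) for e in model.events],
        "citations": [{"doi": c.doi, "role": c.role} for c in model.citations],
    }
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=None)
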