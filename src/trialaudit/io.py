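"""Reading and writing cohort files.

Two canonical on-disk forms hold the same records:

* a flat CSV, one row per trial — sub-item answers in ``ans_<item>_<k>``
  columns with Y/N/NA cells (item 6a repeats per assessed primary outcome
  as ``ans_6a_o<j>_<k>``), scalar fields in prefixed columns
  (``reg_*``, ``art_*``, ``tr_*``), and the variable-length outcome lists
  embedded as JSON cells;
* a nested JSON document (``{"trials": [...]}``) mirroring the in-memory
  model one-to-one, described by :func:`cohort_json_schema`.

Third-party exports (e.g. a deposited extraction spreadsheet) are adapted
through a declarative :class:`ColumnMapping`: source column → canonical
column plus a value-translation table. Records that violate model
invariants are returned flagged, never dropped.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .model import (
    Answer,
    ITEM_SUBITEM_COUNTS,
    SINGLE_VECTOR_ITEMS,
    TrialRecord,
    validate_record,
)

__all__ = ["ColumnMapping", "read_cohort", "write_cohort", "cohort_json_schema"]

logger = logging.getLogger(__name__)

_ANSWER_TO_CELL = {Answer.YES: "Y", Answer.NO: "N", Answer.NA: "NA"}
_CELL_TO_ANSWER = {"Y": Answer.YES, "N": Answer.NO, "NA": Answer.NA}

_SCALAR_COLUMNS = (
    "blinding",
    "reg_registration_date",
    "reg_start_date",
    "reg_imprecise_registration",
    "art_primary_clearly_identified",
    "art_registration_number_reported",
    "art_switch_justified",
    "art_flow_chart_reported",
    "tr_protocol_available",
    "tr_protocol_location",
    "tr_protocol_complete",
    "tr_protocol_in_english",
    "tr_sap_available",
    "tr_sharing_statement",
    "tr_statement_location",
    "tr_access_location_given",
    "tr_timeframe_given",
    "tr_researchers_only",
    "tr_other_restrictions",
    "tr_registry_publication_consistent",
)
_JSON_COLUMNS = (
    "reg_original_outcomes",
    "reg_current_outcomes",
    "art_primary_outcomes",
    "art_outcome_results",
    "art_objective_outcome",
    "art_sample_size_outcome",
    "latent",
)


def _answer_columns(max_6a_outcomes: int) -> list[str]:
    cols = []
    for j in range(1, max_6a_outcomes + 1):
        cols += [f"ans_6a_o{j}_{k}" for k in range(1, 8)]
    for item in SINGLE_VECTOR_ITEMS:
        cols += [f"ans_{item}_{k}" for k in range(1, ITEM_SUBITEM_COUNTS[item] + 1)]
    return cols


def canonical_columns(max_6a_outcomes: int = 1) -> list[str]:
    """Column order of the canonical CSV form."""
    return (
        ["trial_id"]
        + _answer_columns(max_6a_outcomes)
        + list(_SCALAR_COLUMNS)
        + list(_JSON_COLUMNS)
    )


def _is_canonical_column(name: str) -> bool:
    if name == "trial_id" or name in _SCALAR_COLUMNS or name in _JSON_COLUMNS:
        return True
    if not name.startswith("ans_"):
        return False
    return name in set(_answer_columns(max_6a_outcomes=20))


def _bool_cell(value: Optional[bool]) -> str:
    return "" if value is None else ("true" if value else "false")


def _cell_bool(cell: str, column: str) -> Optional[bool]:
    if cell == "":
        return None
    if cell.lower() in ("true", "1", "yes"):
        return True
    if cell.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"column {column}: cannot parse boolean cell {cell!r}")


def _record_to_row(record: TrialRecord) -> dict[str, str]:
    row: dict[str, str] = {"trial_id": record.trial_id}
    for j, ia in enumerate(record.answers_6a, start=1):
        for k, a in enumerate(ia.answers, start=1):
            row[f"ans_6a_o{j}_{k}"] = _ANSWER_TO_CELL[a]
    for item, ia in record.item_answers.items():
        for k, a in enumerate(ia.answers, start=1):
            row[f"ans_{item}_{k}"] = _ANSWER_TO_CELL[a]
    reg, art, tr = record.registry, record.article, record.transparency
    row["blinding"] = record.blinding.value
    row["reg_registration_date"] = reg.registration_date or ""
    row["reg_start_date"] = reg.start_date or ""
    row["reg_imprecise_registration"] = _bool_cell(reg.imprecise_registration)
    row["art_primary_clearly_identified"] = _bool_cell(art.primary_clearly_identified)
    row["art_registration_number_reported"] = _bool_cell(
        art.registration_number_reported
    )
    row["art_switch_justified"] = _bool_cell(art.switch_justified)
    row["art_flow_chart_reported"] = _bool_cell(art.flow_chart_reported)
    row["tr_protocol_available"] = _bool_cell(tr.protocol_available)
    row["tr_protocol_location"] = tr.protocol_location.value
    row["tr_protocol_complete"] = _bool_cell(tr.protocol_complete)
    row["tr_protocol_in_english"] = _bool_cell(tr.protocol_in_english)
    row["tr_sap_available"] = _bool_cell(tr.sap_available)
    row["tr_sharing_statement"] = tr.sharing_statement.value
    row["tr_statement_location"] = tr.statement_location.value
    row["tr_access_location_given"] = _bool_cell(tr.access_location_given)
    row["tr_timeframe_given"] = _bool_cell(tr.timeframe_given)
    row["tr_researchers_only"] = _bool_cell(tr.researchers_only)
    row["tr_other_restrictions"] = _bool_cell(tr.other_restrictions)
    row["tr_registry_publication_consistent"] = _bool_cell(
        tr.registry_publication_consistent
    )

    def dump(obj) -> str:
        return json.dumps(obj, separators=(",", ":"))

    row["reg_original_outcomes"] = dump(
        [o.model_dump(mode="json") for o in reg.original_primary_outcomes]
    )
    row["reg_current_outcomes"] = dump(
        [o.model_dump(mode="json") for o in reg.current_primary_outcomes]
    )
    row["art_primary_outcomes"] = dump(
        [o.model_dump(mode="json") for o in art.primary_outcomes]
    )
    row["art_outcome_results"] = dump(
        [r.model_dump(mode="json") for r in art.all_outcome_results]
    )
    row["art_objective_outcome"] = (
        "" if art.objective_outcome is None
        else dump(art.objective_outcome.model_dump(mode="json"))
    )
    row["art_sample_size_outcome"] = (
        "" if art.sample_size_outcome is None
        else dump(art.sample_size_outcome.model_dump(mode="json"))
    )
    row["latent"] = (
        "" if record.latent is None else dump(record.latent.model_dump(mode="json"))
    )
    return row


def _row_to_record(row: Mapping[str, str]) -> TrialRecord:
    data: dict = {"trial_id": row.get("trial_id", "")}

    item_answers: dict[str, dict] = {}
    answers_6a: list[dict] = []
    j = 1
    while f"ans_6a_o{j}_1" in row and row[f"ans_6a_o{j}_1"] != "":
        answers = [
            _CELL_TO_ANSWER[row[f"ans_6a_o{j}_{k}"]]
            for k in range(1, 8)
            if row.get(f"ans_6a_o{j}_{k}", "") != ""
        ]
        answers_6a.append({"item_id": "6a", "answers": answers})
        j += 1
    for item in SINGLE_VECTOR_ITEMS:
        answers = []
        for k in range(1, ITEM_SUBITEM_COUNTS[item] + 1):
            cell = row.get(f"ans_{item}_{k}", "")
            if cell != "":
                answers.append(_CELL_TO_ANSWER[cell])
        if answers:
            item_answers[item] = {"item_id": item, "answers": answers}
    data["item_answers"] = item_answers
    data["answers_6a"] = answers_6a
    data["blinding"] = row.get("blinding") or "not_reported"

    def jcell(column: str, default):
        cell = row.get(column, "")
        return json.loads(cell) if cell else default

    data["registry"] = {
        "registration_date": row.get("reg_registration_date") or None,
        "start_date": row.get("reg_start_date") or None,
        "imprecise_registration": _cell_bool(
            row.get("reg_imprecise_registration", ""), "reg_imprecise_registration"
        )
        or False,
        "original_primary_outcomes": jcell("reg_original_outcomes", []),
        "current_primary_outcomes": jcell("reg_current_outcomes", []),
    }
    data["article"] = {
        "primary_clearly_identified": _cell_bool(
            row.get("art_primary_clearly_identified", ""),
            "art_primary_clearly_identified",
        )
        if row.get("art_primary_clearly_identified", "") != ""
        else True,
        "primary_outcomes": jcell("art_primary_outcomes", []),
        "all_outcome_results": jcell("art_outcome_results", []),
        "objective_outcome": jcell("art_objective_outcome", None),
        "sample_size_outcome": jcell("art_sample_size_outcome", None),
        "registration_number_reported": _cell_bool(
            row.get("art_registration_number_reported", ""),
            "art_registration_number_reported",
        )
        or False,
        "switch_justified": _cell_bool(
            row.get("art_switch_justified", ""), "art_switch_justified"
        )
        or False,
        "flow_chart_reported": _cell_bool(
            row.get("art_flow_chart_reported", ""), "art_flow_chart_reported"
        )
        or False,
    }
    data["transparency"] = {
        "protocol_available": _cell_bool(
            row.get("tr_protocol_available", ""), "tr_protocol_available"
        )
        or False,
        "protocol_location": row.get("tr_protocol_location") or "none",
        "protocol_complete": _cell_bool(
            row.get("tr_protocol_complete", ""), "tr_protocol_complete"
        ),
        "protocol_in_english": _cell_bool(
            row.get("tr_protocol_in_english", ""), "tr_protocol_in_english"
        ),
        "sap_available": _cell_bool(row.get("tr_sap_available", ""), "tr_sap_available")
        or False,
        "sharing_statement": row.get("tr_sharing_statement") or "no_statement",
        "statement_location": row.get("tr_statement_location") or "none",
        "access_location_given": _cell_bool(
            row.get("tr_access_location_given", ""), "tr_access_location_given"
        )
        or False,
        "timeframe_given": _cell_bool(
            row.get("tr_timeframe_given", ""), "tr_timeframe_given"
        )
        or False,
        "researchers_only": _cell_bool(
            row.get("tr_researchers_only", ""), "tr_researchers_only"
        )
        or False,
        "other_restrictions": _cell_bool(
            row.get("tr_other_restrictions", ""), "tr_other_restrictions"
        )
        or False,
        "registry_publication_consistent": _cell_bool(
            row.get("tr_registry_publication_consistent", ""),
            "tr_registry_publication_consistent",
        ),
    }
    data["latent"] = jcell("latent", None)
    return TrialRecord.model_validate(data)


class ColumnMapping:
    """Declarative adapter from a third-party export to the canonical CSV
    columns.

    The mapping document is JSON::

        {"columns": {"<source column>": {"target": "<canonical column>",
                                         "map": {"2": "N", ...},
                                         "default": "<cell>"}}}

    ``map`` translates observed source values; values absent from the table
    fall back to ``default`` when given, otherwise pass through unchanged.
    Source columns not mentioned in the mapping are ignored with a logged
    warning.
    """

    def __init__(self, columns: Mapping[str, Mapping]):
        self.columns: dict[str, dict] = {}
        for source, spec in columns.items():
            target = spec["target"]
            if not _is_canonical_column(target):
                raise ValueError(
                    f"mapping for {source!r}: {target!r} is not a canonical column"
                )
            self.columns[source] = {
                "target": target,
                "map": dict(spec.get("map", {})),
                "default": spec.get("default"),
            }
        targets = [s["target"] for s in self.columns.values()]
        if "trial_id" not in targets:
            raise ValueError("unmapped required column: trial_id")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColumnMapping":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(doc["columns"])

    def apply(self, row: Mapping[str, str]) -> dict[str, str]:
        out: dict[str, str] = {}
        for source, value in row.items():
            spec = self.columns.get(source)
            if spec is None:
                continue
            if value in spec["map"]:
                value = spec["map"][value]
            elif spec["map"] and spec["default"] is not None:
                value = spec["default"]
            out[spec["target"]] = value
        return out

    def unknown_columns(self, header: Sequence[str]) -> list[str]:
        return [c for c in header if c not in self.columns]


def read_cohort(
    path: Union[str, Path],
    mapping: Optional[ColumnMapping] = None,
) -> list[TrialRecord]:
    """Read a cohort file (canonical CSV or JSON; a mapped CSV when a
    :class:`ColumnMapping` is given).

    Every row yields a record; records violating model invariants carry the
    violation descriptions on ``record.violations`` instead of being
    dropped.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if mapping is not None:
            raise ValueError("column mappings apply to CSV input only")
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        records = [TrialRecord.model_validate(t) for t in doc["trials"]]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if mapping is not None and reader.fieldnames:
                unknown = mapping.unknown_columns(reader.fieldnames)
                if unknown:
                    logger.warning(
                        "ignoring unmapped source columns: %s", ", ".join(unknown)
                    )
            rows = list(reader)
        if mapping is not None:
            rows = [mapping.apply(r) for r in rows]
        records = [_row_to_record(r) for r in rows]
    flagged = 0
    for rec in records:
        problems = validate_record(rec)
        rec._violations = problems
        if problems:
            flagged += 1
    if flagged:
        logger.warning("%d of %d records violate invariants", flagged, len(records))
    return records


def write_cohort(
    records: Sequence[TrialRecord],
    path: Union[str, Path],
    format: str = "csv",
) -> Path:
    """Write records in canonical form; ``read_cohort`` on the output
    reproduces them field-for-field."""
    path = Path(path)
    if format == "json":
        doc = {"trials": [r.model_dump(mode="json") for r in records]}
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return path
    if format != "csv":
        raise ValueError(f"unknown cohort format: {format!r}")
    max_6a = max((len(r.answers_6a) for r in records), default=1) or 1
    columns = canonical_columns(max_6a)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, restval="")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))
    return path


def cohort_json_schema() -> dict:
    """JSON Schema for the nested cohort document."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "Trial audit cohort",
        "type": "object",
        "required": ["trials"],
        "properties": {
            "trials": {"type": "array", "items": TrialRecord.model_json_schema()}
        },
    }
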