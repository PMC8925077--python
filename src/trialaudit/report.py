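"""Cohort-level aggregation of per-trial audit verdicts.

Runs the full per-trial pipeline (completeness scoring, transparency
indicators, switch classification, favorability) and tallies every
indicator with its proper denominator — all trials, blinded trials,
protocol-available trials, sharing-willing trials, switch trials, or
assessable switch trials. Percentages follow the reporting convention of
the audited literature: integers, ties rounded up.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .favorability import assess_favorability
from .model import (
    BlindingStatus,
    Favorability,
    ItemRating,
    Location,
    SWITCH_CATEGORIES,
    SharingStatement,
    SwitchCategory,
    TriggerRule,
    TrialRecord,
)
from .scoring import blend_ratings, rate_trial_overall, score_trial
from .switching import (
    OutcomeOverride,
    classify_switch,
    match_outcomes,
    pick_registry_outcomes,
)
from .transparency import TransparencyIndicators, summarize_transparency

__all__ = [
    "percent",
    "Entry",
    "CohortSummary",
    "TrialVerdicts",
    "evaluate_trial",
    "summarize_rows",
    "summarize_cohort",
    "render_report",
    "check_block_sums",
]


def percent(count: int, denominator: int) -> int:
    """Integer percentage, nearest with ties rounded up (37.5 → 38)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside [0, {denominator}]")
    return (200 * count + denominator) // (2 * denominator)


@dataclass(frozen=True)
class Entry:
    count: int
    denominator: int

    @property
    def percent(self) -> Optional[int]:
        return None if self.denominator == 0 else percent(self.count, self.denominator)

    @property
    def fraction(self) -> Optional[float]:
        return None if self.denominator == 0 else self.count / self.denominator


@dataclass
class CohortSummary:
    """Counts and percentages for every audited indicator, grouped into
    blocks (documentation, data sharing, completeness, selective
    reporting)."""

    n: int
    blocks: dict[str, dict[str, Entry]] = field(default_factory=dict)

    def entry(self, block: str, name: str) -> Entry:
        return self.blocks[block][name]

    def fractions(self) -> dict[str, float]:
        """Flat ``block.indicator -> fraction`` view (zero-denominator
        entries map to 0.0)."""
        return {
            f"{block}.{name}": (e.fraction if e.fraction is not None else 0.0)
            for block, entries in self.blocks.items()
            for name, e in entries.items()
        }

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "blocks": {
                block: {
                    name: {
                        "count": e.count,
                        "denominator": e.denominator,
                        "percent": e.percent,
                        "fraction": e.fraction,
                    }
                    for name, e in entries.items()
                }
                for block, entries in self.blocks.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortSummary":
        return cls(
            n=data["n"],
            blocks={
                block: {
                    name: Entry(v["count"], v["denominator"])
                    for name, v in entries.items()
                }
                for block, entries in data["blocks"].items()
            },
        )


@dataclass
class TrialVerdicts:
    """Every per-trial verdict the cohort summary tallies."""

    trial_id: str
    ratings: dict[str, ItemRating]
    overall: ItemRating
    flow_combined: ItemRating
    blinding: BlindingStatus
    flow_chart: bool
    registration_number: bool
    retrospective: Optional[bool]
    switch_category: SwitchCategory
    favorability: Optional[Favorability]
    trigger: Optional[TriggerRule]
    switch_justified: bool
    transparency: TransparencyIndicators


def evaluate_trial(
    record: TrialRecord, overrides: Sequence[OutcomeOverride] = ()
) -> TrialVerdicts:
    """Run scoring, transparency, switch and favorability on one record."""
    ratings = score_trial(record)
    category = classify_switch(record, overrides)
    favorability: Optional[Favorability] = None
    trigger: Optional[TriggerRule] = None
    if category in SWITCH_CATEGORIES:
        match = match_outcomes(
            pick_registry_outcomes(record.registry),
            record.article.primary_outcomes,
            overrides,
        )
        verdict = assess_favorability(
            category, match, record.article.all_outcome_results
        )
        favorability, trigger = verdict.value, verdict.trigger
    try:
        from .switching import is_retrospective

        retrospective: Optional[bool] = is_retrospective(
            record.registry.registration_date, record.registry.start_date
        )
    except ValueError:
        retrospective = None
    return TrialVerdicts(
        trial_id=record.trial_id,
        ratings=ratings,
        overall=rate_trial_overall(ratings),
        flow_combined=blend_ratings([ratings["13a"], ratings["13b"]]),
        blinding=record.blinding,
        flow_chart=record.article.flow_chart_reported,
        registration_number=record.article.registration_number_reported,
        retrospective=retrospective,
        switch_category=category,
        favorability=favorability,
        trigger=trigger,
        switch_justified=record.article.switch_justified,
        transparency=summarize_transparency(record),
    )


# ---------------------------------------------------------------------------
# Denominator registry: each indicator declares the subpopulation its
# percentage is computed over, so the mixed denominators of the summary
# table are explicit and testable.

_DENOMINATORS: dict[str, Callable[[TrialVerdicts], bool]] = {
    "all": lambda r: True,
    "blinded": lambda r: r.blinding is BlindingStatus.BLINDED,
    "protocol_available": lambda r: r.transparency.protocol_available,
    "willing": lambda r: r.transparency.sharing_statement is SharingStatement.WILLING,
    "switched": lambda r: r.switch_category in SWITCH_CATEGORIES,
    "assessable_switch": lambda r: r.favorability
    in (Favorability.FAVORS_SIGNIFICANCE, Favorability.DOES_NOT_FAVOR),
}


def _rating_pred(key: str, value: ItemRating) -> Callable[[TrialVerdicts], bool]:
    return lambda r: r.ratings[key] is value


_C, _P, _N = ItemRating.COMPLETE, ItemRating.PARTIAL, ItemRating.NOT_REPORTED

#: (block, indicator, predicate, denominator key)
INDICATOR_TABLE: list[tuple[str, str, Callable[[TrialVerdicts], bool], str]] = [
    ("documentation", "protocol_available",
     lambda r: r.transparency.protocol_available, "all"),
    ("documentation", "protocol_in_publication",
     lambda r: r.transparency.protocol_location is Location.PUBLICATION, "all"),
    ("documentation", "protocol_in_registry",
     lambda r: r.transparency.protocol_location is Location.REGISTRY, "all"),
    ("documentation", "protocol_in_both",
     lambda r: r.transparency.protocol_location is Location.BOTH, "all"),
    ("documentation", "protocol_complete",
     lambda r: r.transparency.protocol_complete is True, "protocol_available"),
    ("documentation", "protocol_in_english",
     lambda r: r.transparency.protocol_in_english is True, "protocol_available"),
    ("documentation", "sap_available",
     lambda r: r.transparency.sap_available, "all"),

    ("data_sharing", "willing_to_share",
     lambda r: r.transparency.sharing_statement is SharingStatement.WILLING, "all"),
    ("data_sharing", "statement_in_publication",
     lambda r: r.transparency.sharing_statement is SharingStatement.WILLING
     and r.transparency.statement_location is Location.PUBLICATION, "all"),
    ("data_sharing", "statement_in_registry",
     lambda r: r.transparency.sharing_statement is SharingStatement.WILLING
     and r.transparency.statement_location is Location.REGISTRY, "all"),
    ("data_sharing", "statement_in_both",
     lambda r: r.transparency.sharing_statement is SharingStatement.WILLING
     and r.transparency.statement_location is Location.BOTH, "all"),
    ("data_sharing", "not_willing_to_share",
     lambda r: r.transparency.sharing_statement is SharingStatement.NOT_WILLING, "all"),
    ("data_sharing", "no_statement",
     lambda r: r.transparency.sharing_statement is SharingStatement.NO_STATEMENT, "all"),
    ("data_sharing", "access_location_given",
     lambda r: r.transparency.access_location_given is True, "willing"),
    ("data_sharing", "timeframe_given",
     lambda r: r.transparency.timeframe_given is True, "willing"),
    ("data_sharing", "researchers_only",
     lambda r: r.transparency.researchers_only is True, "willing"),
    ("data_sharing", "other_restrictions",
     lambda r: r.transparency.other_restrictions is True, "willing"),

    ("completeness", "overall_complete", lambda r: r.overall is _C, "all"),
    ("completeness", "overall_partial", lambda r: r.overall is _P, "all"),
    ("completeness", "overall_not_reported", lambda r: r.overall is _N, "all"),
    ("completeness", "primary_outcome_complete", _rating_pred("6a", _C), "all"),
    ("completeness", "primary_outcome_partial", _rating_pred("6a", _P), "all"),
    ("completeness", "primary_outcome_not_reported", _rating_pred("6a", _N), "all"),
    ("completeness", "sequence_generation_complete", _rating_pred("8a", _C), "all"),
    ("completeness", "allocation_concealment_complete", _rating_pred("9", _C), "all"),
    ("completeness", "blinded_trials",
     lambda r: r.blinding is BlindingStatus.BLINDED, "all"),
    ("completeness", "unblinded_trials",
     lambda r: r.blinding is BlindingStatus.UNBLINDED, "all"),
    ("completeness", "blinding_status_unclear",
     lambda r: r.blinding is BlindingStatus.NOT_REPORTED, "all"),
    ("completeness", "blinding_complete", _rating_pred("11", _C), "blinded"),
    ("completeness", "flow_chart_available", lambda r: r.flow_chart, "all"),
    ("completeness", "participant_flow_complete",
     lambda r: r.flow_combined is _C, "all"),
    ("completeness", "participant_flow_partial",
     lambda r: r.flow_combined is _P, "all"),
    ("completeness", "participant_flow_not_reported",
     lambda r: r.flow_combined is _N, "all"),
    ("completeness", "primary_results_complete", _rating_pred("17a", _C), "all"),
    ("completeness", "primary_results_partial", _rating_pred("17a", _P), "all"),
    ("completeness", "primary_results_not_reported", _rating_pred("17a", _N), "all"),
    ("completeness", "harms_complete", _rating_pred("19", _C), "all"),
    ("completeness", "harms_partial", _rating_pred("19", _P), "all"),
    ("completeness", "harms_not_reported", _rating_pred("19", _N), "all"),
    ("completeness", "registration_number_reported",
     lambda r: r.registration_number, "all"),

    ("selective_reporting", "retrospective_registration",
     lambda r: r.retrospective is True, "all"),
    ("selective_reporting", "switch_non_assessable",
     lambda r: r.switch_category is SwitchCategory.NON_ASSESSABLE, "all"),
    ("selective_reporting", "imprecise_registration",
     lambda r: r.switch_category is SwitchCategory.IMPRECISE_REGISTRATION, "all"),
    ("selective_reporting", "no_switch",
     lambda r: r.switch_category is SwitchCategory.NO_SWITCH, "all"),
    ("selective_reporting", "switched",
     lambda r: r.switch_category in SWITCH_CATEGORIES, "all"),
    ("selective_reporting", "switch_add_remove",
     lambda r: r.switch_category is SwitchCategory.SWITCH_ADD_REMOVE, "switched"),
    ("selective_reporting", "switch_definition",
     lambda r: r.switch_category is SwitchCategory.SWITCH_DEFINITION, "switched"),
    ("selective_reporting", "switch_combination",
     lambda r: r.switch_category is SwitchCategory.SWITCH_COMBINATION, "switched"),
    ("selective_reporting", "favorability_assessable",
     lambda r: r.favorability
     in (Favorability.FAVORS_SIGNIFICANCE, Favorability.DOES_NOT_FAVOR), "switched"),
    ("selective_reporting", "favors_significance",
     lambda r: r.favorability is Favorability.FAVORS_SIGNIFICANCE,
     "assessable_switch"),
    ("selective_reporting", "switch_justified",
     lambda r: r.switch_justified, "switched"),
]

#: indicator groups whose counts must sum to their denominator
CATEGORICAL_GROUPS: list[tuple[str, tuple[str, ...]]] = [
    ("data_sharing", ("willing_to_share", "not_willing_to_share", "no_statement")),
    ("completeness", ("overall_complete", "overall_partial", "overall_not_reported")),
    ("completeness", ("primary_outcome_complete", "primary_outcome_partial",
                      "primary_outcome_not_reported")),
    ("completeness", ("blinded_trials", "unblinded_trials", "blinding_status_unclear")),
    ("completeness", ("participant_flow_complete", "participant_flow_partial",
                      "participant_flow_not_reported")),
    ("completeness", ("primary_results_complete", "primary_results_partial",
                      "primary_results_not_reported")),
    ("completeness", ("harms_complete", "harms_partial", "harms_not_reported")),
    ("selective_reporting", ("switch_non_assessable", "imprecise_registration",
                             "no_switch", "switched")),
    ("selective_reporting", ("switch_add_remove", "switch_definition",
                             "switch_combination")),
]


def summarize_rows(rows: Sequence[TrialVerdicts]) -> CohortSummary:
    """Tally per-trial verdicts into a :class:`CohortSummary`."""
    if not rows:
        raise ValueError("cannot summarize an empty cohort")
    denom_counts = {key: sum(1 for r in rows if pred(r)) for key, pred in _DENOMINATORS.items()}
    summary = CohortSummary(n=len(rows))
    for block, name, pred, denom_key in INDICATOR_TABLE:
        count = sum(1 for r in rows if pred(r) and _DENOMINATORS[denom_key](r))
        summary.blocks.setdefault(block, {})[name] = Entry(
            count, denom_counts[denom_key]
        )
    return summary


def summarize_cohort(
    records: Sequence[TrialRecord],
    overrides_by_trial: Optional[Mapping[str, Sequence[OutcomeOverride]]] = None,
) -> CohortSummary:
    """Run the full pipeline on every record and aggregate."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    overrides_by_trial = overrides_by_trial or {}
    rows = [
        evaluate_trial(rec, overrides_by_trial.get(rec.trial_id, ()))
        for rec in records
    ]
    return summarize_rows(rows)


def check_block_sums(summary: CohortSummary) -> list[str]:
    """Verify that each categorical group's counts sum to the group's
    denominator; returns violation descriptions."""
    problems = []
    for block, names in CATEGORICAL_GROUPS:
        entries = [summary.blocks[block][n] for n in names]
        denoms = {e.denominator for e in entries}
        total = sum(e.count for e in entries)
        if len(denoms) != 1 or total != next(iter(denoms)):
            problems.append(
                f"{block}: {'+'.join(names)} = {total}, denominator {denoms}"
            )
    return problems


def render_report(summary: CohortSummary, format: str) -> str:
    """Render a summary as lossless JSON, a flat CSV, or a markdown table."""
    if format == "json":
        return json.dumps(summary.to_dict(), indent=2)
    if format == "csv":
        buf = _io.StringIO()
        buf.write("block,indicator,count,denominator,percent\n")
        for block, entries in summary.blocks.items():
            for name, e in entries.items():
                pct = "" if e.percent is None else e.percent
                buf.write(f"{block},{name},{e.count},{e.denominator},{pct}\n")
        return buf.getvalue()
    if format == "markdown":
        lines = [f"# Cohort summary (n={summary.n})", ""]
        for block, entries in summary.blocks.items():
            lines.append(f"## {block.replace('_', ' ').title()}")
            lines.append("")
            lines.append("| Indicator | Count | Denominator | % |")
            lines.append("| --- | ---: | ---: | ---: |")
            for name, e in entries.items():
                pct = "–" if e.percent is None else str(e.percent)
                lines.append(
                    f"| {name.replace('_', ' ')} | {e.count} | {e.denominator} | {pct} |"
                )
            lines.append("")
        return "\n".join(lines)
    raise ValueError(f"unknown report format: {format!r}")
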