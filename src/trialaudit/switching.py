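"""Selective-reporting checks: retrospective registration and
primary-outcome switching between registry and publication.

A *switch* is any discrepancy between the primary outcome(s) registered for
a trial and those reported as primary in the article: an added or removed
primary outcome, a change of definition (time frame, metric, or an
annotator-flagged definitional change), or a combination of both. Trials
whose registered outcome is too vague to compare are classified as
*imprecise registration* and excluded from switching; trials whose article
names no clear primary outcome are *non-assessable*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .model import (
    OutcomeSpec,
    PartialDate,
    RegistryInfo,
    SwitchCategory,
    TrialRecord,
    normalize_label,
)

__all__ = [
    "is_retrospective",
    "pick_registry_outcomes",
    "OutcomeOverride",
    "MatchedPair",
    "MatchSet",
    "match_outcomes",
    "classify_switch",
]


def _as_date(value: Union[str, PartialDate, None]) -> Optional[PartialDate]:
    if value is None:
        return None
    if isinstance(value, PartialDate):
        return value
    return PartialDate.parse(value)


def is_retrospective(
    registration_date: Union[str, PartialDate, None],
    start_date: Union[str, PartialDate, None],
) -> bool:
    """True iff the trial was registered strictly after its start date.

    Dates of mixed precision compare at the coarser one (month), so a trial
    registered later in its starting month does not count as retrospective
    when either date lacks a day.
    """
    reg = _as_date(registration_date)
    start = _as_date(start_date)
    if reg is None or start is None:
        raise ValueError("registration status non-assessable: missing date")
    return reg.is_after(start)


def pick_registry_outcomes(registry: RegistryInfo) -> list[OutcomeSpec]:
    """The registered primary outcomes used for switch comparison: the ones
    labelled *original*, falling back to the *current* ones only when no
    original list is available."""
    if registry.original_primary_outcomes:
        return list(registry.original_primary_outcomes)
    if registry.current_primary_outcomes:
        return list(registry.current_primary_outcomes)
    raise ValueError("registry lists no primary outcome (original or current)")


@dataclass(frozen=True)
class OutcomeOverride:
    """Annotator-supplied assertion that two differently-worded outcome
    labels denote the same outcome, optionally flagging a definitional
    change that plain field comparison cannot see (e.g. a changed
    assessment scale)."""

    registered_variable: str
    article_variable: str
    definition_changed: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (
            normalize_label(self.registered_variable),
            normalize_label(self.article_variable),
        )


@dataclass(frozen=True)
class MatchedPair:
    registered: OutcomeSpec
    article: OutcomeSpec
    changed_fields: frozenset[str]  # subset of {"time_frame", "metric", "definition"}


@dataclass
class MatchSet:
    matched_pairs: list[MatchedPair] = field(default_factory=list)
    unmatched_registered: list[OutcomeSpec] = field(default_factory=list)
    unmatched_article: list[OutcomeSpec] = field(default_factory=list)

    @property
    def any_added_or_removed(self) -> bool:
        return bool(self.unmatched_registered or self.unmatched_article)

    @property
    def any_definition_change(self) -> bool:
        return any(p.changed_fields for p in self.matched_pairs)


def _norm_optional(text: Optional[str]) -> Optional[str]:
    return None if text is None else normalize_label(text)


def _changed_fields(
    registered: OutcomeSpec, article: OutcomeSpec, definition_changed: bool
) -> frozenset[str]:
    changed = set()
    if _norm_optional(registered.time_frame) != _norm_optional(article.time_frame):
        changed.add("time_frame")
    if _norm_optional(registered.analysis_metric) != _norm_optional(
        article.analysis_metric
    ):
        changed.add("metric")
    if definition_changed:
        changed.add("definition")
    return frozenset(changed)


def match_outcomes(
    registered: Sequence[OutcomeSpec],
    published: Sequence[OutcomeSpec],
    overrides: Sequence[OutcomeOverride] = (),
) -> MatchSet:
    """Pair registered with published primary outcomes.

    Outcomes pair on their normalized variable label, or through an explicit
    override asserting equivalence; no fuzzy matching. Each outcome lands in
    exactly one bucket: a matched pair (with the set of fields that changed)
    or one of the unmatched lists.
    """
    override_map = {ov.key: ov for ov in overrides}
    result = MatchSet()
    remaining = list(published)
    for reg in registered:
        reg_norm = reg.variable_normalized
        hit = None
        for art in remaining:
            art_norm = art.variable_normalized
            ov = override_map.get((reg_norm, art_norm))
            if reg_norm == art_norm or ov is not None:
                hit = (art, ov.definition_changed if ov else False)
                break
        if hit is None:
            result.unmatched_registered.append(reg)
        else:
            art, definition_changed = hit
            remaining.remove(art)
            result.matched_pairs.append(
                MatchedPair(reg, art, _changed_fields(reg, art, definition_changed))
            )
    result.unmatched_article = remaining
    return result


def classify_switch(
    record: TrialRecord, overrides: Sequence[OutcomeOverride] = ()
) -> SwitchCategory:
    """Classify one trial's registry-vs-article primary-outcome consistency.

    Precedence: no clear primary outcome in the article → non-assessable;
    imprecise registered outcome → imprecise registration; otherwise the
    added/removed flag A and definition-change flag D of the match set map
    onto {no_switch, add/remove, definition change, combination}.
    """
    if not record.article.primary_clearly_identified:
        return SwitchCategory.NON_ASSESSABLE
    if record.registry.imprecise_registration:
        return SwitchCategory.IMPRECISE_REGISTRATION
    match = match_outcomes(
        pick_registry_outcomes(record.registry),
        record.article.primary_outcomes,
        overrides,
    )
    added_removed = match.any_added_or_removed
    definition = match.any_definition_change
    if added_removed and definition:
        return SwitchCategory.SWITCH_COMBINATION
    if added_removed:
        return SwitchCategory.SWITCH_ADD_REMOVE
    if definition:
        return SwitchCategory.SWITCH_DEFINITION
    return SwitchCategory.NO_SWITCH
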