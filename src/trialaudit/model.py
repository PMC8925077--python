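"""Domain model for the trial-transparency audit.

The types here mirror a structured data-extraction form for randomized
controlled trials registered on a public registry: CONSORT sub-item answers
for the eleven most important, frequently incompletely reported items
(the COBPeer checklist), registered and published primary-outcome
specifications, per-outcome results, registration/start dates, and
protocol / data-sharing (transparency) fields.

Everything downstream — completeness scoring, outcome-switch
classification, favorability verdicts, cohort aggregation — consumes
:class:`TrialRecord` instances and nothing else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Annotated, Optional

from pydantic import BaseModel, Field, PrivateAttr, StringConstraints

__all__ = [
    "Answer",
    "ItemRating",
    "BlindingStatus",
    "OutcomeRole",
    "OutcomeType",
    "OutcomeSource",
    "Direction",
    "TrialDesign",
    "SharingStatement",
    "Location",
    "SwitchCategory",
    "SignificanceClass",
    "Favorability",
    "TriggerRule",
    "ItemAnswers",
    "OutcomeSpec",
    "OutcomeResult",
    "RegistryInfo",
    "ArticleInfo",
    "TransparencyInfo",
    "LatentLabels",
    "TrialRecord",
    "PartialDate",
    "ITEM_SUBITEM_COUNTS",
    "SINGLE_VECTOR_ITEMS",
    "SCORED_ITEMS",
    "normalize_label",
    "validate_record",
]


class Answer(str, Enum):
    """Sub-item answer: was this element adequately reported?

    ``NA`` means "non-assessable" (the sub-item does not apply, e.g. the
    time point of a survival analysis) — never "missing data".
    """

    YES = "yes"
    NO = "no"
    NA = "na"


class ItemRating(str, Enum):
    """Three-level completeness verdict for one checklist item (or a trial)."""

    COMPLETE = "complete"
    PARTIAL = "partial"
    NOT_REPORTED = "not_reported"
    NOT_APPLICABLE = "not_applicable"


class BlindingStatus(str, Enum):
    BLINDED = "blinded"
    UNBLINDED = "unblinded"
    NOT_REPORTED = "not_reported"


class OutcomeRole(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


class OutcomeType(str, Enum):
    EFFICACY = "efficacy"
    SAFETY = "safety"


class OutcomeSource(str, Enum):
    REGISTRY_ORIGINAL = "registry_original"
    REGISTRY_CURRENT = "registry_current"
    ARTICLE = "article"


class Direction(str, Enum):
    SUPPORTS_INTERVENTION = "supports_intervention"
    REFUTES_INTERVENTION = "refutes_intervention"
    UNCLEAR = "unclear"


class TrialDesign(str, Enum):
    SUPERIORITY = "superiority"
    EQUIVALENCE = "equivalence"
    NON_INFERIORITY = "non_inferiority"


class SharingStatement(str, Enum):
    WILLING = "willing"
    NOT_WILLING = "not_willing"
    NO_STATEMENT = "no_statement"


class Location(str, Enum):
    PUBLICATION = "publication"
    REGISTRY = "registry"
    BOTH = "both"
    NONE = "none"


class SwitchCategory(str, Enum):
    """Per-trial verdict on registry-vs-article primary-outcome consistency."""

    NO_SWITCH = "no_switch"
    SWITCH_ADD_REMOVE = "switch_add_remove"
    SWITCH_DEFINITION = "switch_definition"
    SWITCH_COMBINATION = "switch_combination"
    IMPRECISE_REGISTRATION = "imprecise_registration"
    NON_ASSESSABLE = "non_assessable"


SWITCH_CATEGORIES = frozenset(
    {
        SwitchCategory.SWITCH_ADD_REMOVE,
        SwitchCategory.SWITCH_DEFINITION,
        SwitchCategory.SWITCH_COMBINATION,
    }
)


class SignificanceClass(str, Enum):
    SIGNIFICANT = "significant"
    NON_SIGNIFICANT = "non_significant"
    UNCLEAR = "unclear"


class Favorability(str, Enum):
    FAVORS_SIGNIFICANCE = "favors_significance"
    DOES_NOT_FAVOR = "does_not_favor"
    NON_ASSESSABLE = "non_assessable"


class TriggerRule(str, Enum):
    """Which rule made a switch count as favoring significance.

    ``A`` — a new statistically significant efficacy primary was introduced;
    ``B`` — a non-significant efficacy primary was omitted or demoted to
    secondary; ``C`` — a new non-significant safety primary was introduced.
    """

    A = "a"
    B = "b"
    C = "c"
    NONE = "none"


#: Fixed sub-item counts per checklist item. Item 6a is answered once per
#: assessed primary outcome (7 sub-items each); item 11 itself is the
#: blinding-status question and carries no answer vector of its own.
ITEM_SUBITEM_COUNTS: dict[str, int] = {
    "6a": 7,
    "8a": 1,
    "9": 1,
    "11a": 2,
    "11b": 1,
    "13a": 3,
    "13b": 4,
    "17a": 3,
    "19": 6,
    "23": 1,
}

#: Items stored as a single answer vector on the record (6a is per-outcome).
SINGLE_VECTOR_ITEMS: tuple[str, ...] = (
    "8a",
    "9",
    "11a",
    "11b",
    "13a",
    "13b",
    "17a",
    "19",
    "23",
)

#: Item keys entering the overall trial rating ("11" is the combined
#: blinding rating rolled up from 11a+11b, not_applicable when unblinded).
SCORED_ITEMS: tuple[str, ...] = (
    "6a",
    "8a",
    "9",
    "11",
    "13a",
    "13b",
    "17a",
    "19",
    "23",
)

_WS = re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Normalize a free-text outcome label for matching (trim, case-fold,
    collapse internal whitespace)."""
    return _WS.sub(" ", text.strip()).casefold()


# Dates are ISO strings carrying their own precision: "YYYY-MM" (month) or
# "YYYY-MM-DD" (day). Registry exports often omit the day; storing the
# coarse form avoids fabricating one.
DateStr = Annotated[str, StringConstraints(pattern=r"^\d{4}-\d{2}(-\d{2})?$")]


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date of day or month precision."""

    year: int
    month: int
    day: Optional[int] = None

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        parts = text.split("-")
        if len(parts) == 2:
            return cls(int(parts[0]), int(parts[1]))
        if len(parts) == 3:
            return cls(int(parts[0]), int(parts[1]), int(parts[2]))
        raise ValueError(f"not an ISO date or year-month: {text!r}")

    def __str__(self) -> str:
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def is_after(self, other: "PartialDate") -> bool:
        """Strictly-after comparison at the coarser of the two precisions."""
        if self.day is None or other.day is None:
            return (self.year, self.month) > (other.year, other.month)
        return (self.year, self.month, self.day) > (
            other.year,
            other.month,
            other.day,
        )


class ItemAnswers(BaseModel):
    """Ordered sub-item answers for one checklist item.

    Length is *not* enforced at construction so that malformed extractions
    can be represented and reported by :func:`validate_record`.
    """

    item_id: str
    answers: list[Answer]


class OutcomeSpec(BaseModel):
    """A primary/secondary outcome's definition as extracted from the
    registry or the article."""

    variable: str
    assessment_method: Optional[str] = None
    analysis_metric: Optional[str] = None
    time_frame: Optional[str] = None
    role: OutcomeRole = OutcomeRole.PRIMARY
    outcome_type: OutcomeType = OutcomeType.EFFICACY
    source: OutcomeSource = OutcomeSource.ARTICLE

    @property
    def variable_normalized(self) -> str:
        return normalize_label(self.variable)


class OutcomeResult(BaseModel):
    """A published result for one outcome.

    ``within_margin`` replaces the p-value criterion for equivalence and
    non-inferiority designs; ``summary_reported`` records whether the
    article reports any result for the outcome at all.
    """

    outcome: OutcomeSpec
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    direction: Direction = Direction.UNCLEAR
    design: TrialDesign = TrialDesign.SUPERIORITY
    within_margin: Optional[bool] = None
    summary_reported: bool = True


class RegistryInfo(BaseModel):
    registration_date: Optional[DateStr] = None
    start_date: Optional[DateStr] = None
    original_primary_outcomes: list[OutcomeSpec] = Field(default_factory=list)
    current_primary_outcomes: list[OutcomeSpec] = Field(default_factory=list)
    #: annotator judgment that the registered outcome is too imprecise to
    #: compare with the published one
    imprecise_registration: bool = False


class ArticleInfo(BaseModel):
    primary_clearly_identified: bool = True
    primary_outcomes: list[OutcomeSpec] = Field(default_factory=list)
    all_outcome_results: list[OutcomeResult] = Field(default_factory=list)
    #: outcome used for the primary objective (fallback for item 6a)
    objective_outcome: Optional[OutcomeSpec] = None
    #: outcome used for the sample-size calculation (fallback for item 6a)
    sample_size_outcome: Optional[OutcomeSpec] = None
    registration_number_reported: bool = False
    switch_justified: bool = False
    #: descriptive field, reported separately from the item 13a score
    flow_chart_reported: bool = False


class TransparencyInfo(BaseModel):
    protocol_available: bool = False
    protocol_location: Location = Location.NONE
    #: protocol is complete, i.e. not abbreviated or redacted
    protocol_complete: Optional[bool] = None
    protocol_in_english: Optional[bool] = None
    sap_available: bool = False
    sharing_statement: SharingStatement = SharingStatement.NO_STATEMENT
    statement_location: Location = Location.NONE
    access_location_given: bool = False
    timeframe_given: bool = False
    researchers_only: bool = False
    other_restrictions: bool = False
    registry_publication_consistent: Optional[bool] = None


class LatentLabels(BaseModel):
    """Ground-truth verdicts a synthetic record was generated to realize.

    Present on synthetic records only; used by round-trip tests that check
    the pipeline reproduces every latent label exactly.
    """

    item_ratings: dict[str, ItemRating]
    overall: ItemRating
    blinding: BlindingStatus
    retrospective: bool
    switch_category: SwitchCategory
    favorability: Optional[Favorability] = None
    trigger_rule: Optional[TriggerRule] = None


class TrialRecord(BaseModel):
    """One trial's full structured extraction."""

    trial_id: str
    item_answers: dict[str, ItemAnswers] = Field(default_factory=dict)
    #: item 6a answers, one 7-long vector per assessed primary outcome
    answers_6a: list[ItemAnswers] = Field(default_factory=list)
    blinding: BlindingStatus = BlindingStatus.NOT_REPORTED
    registry: RegistryInfo = Field(default_factory=RegistryInfo)
    article: ArticleInfo = Field(default_factory=ArticleInfo)
    transparency: TransparencyInfo = Field(default_factory=TransparencyInfo)
    latent: Optional[LatentLabels] = None

    _violations: list[str] = PrivateAttr(default_factory=list)

    @property
    def violations(self) -> list[str]:
        """Validation violations attached at import time (may be stale;
        recompute with :func:`validate_record`)."""
        return self._violations


def _validate_outcome(spec: OutcomeSpec, where: str, problems: list[str]) -> None:
    if not spec.variable.strip():
        problems.append(f"{where}: outcome variable is empty")


def validate_record(record: TrialRecord) -> list[str]:
    """Check every cross-field invariant; return one description per
    violation (an empty list means the record is internally consistent).

    Violations are data, not exceptions: importers attach them to records
    rather than dropping rows.
    """
    problems: list[str] = []

    if not record.trial_id.strip():
        problems.append("trial_id: must be non-empty")

    for item_id, ia in record.item_answers.items():
        if item_id not in SINGLE_VECTOR_ITEMS:
            problems.append(f"item_answers: unknown item {item_id!r}")
            continue
        expected = ITEM_SUBITEM_COUNTS[item_id]
        if ia.item_id != item_id:
            problems.append(
                f"item_answers[{item_id}]: item_id field says {ia.item_id!r}"
            )
        if len(ia.answers) != expected:
            problems.append(
                f"item {item_id} expects {expected} sub-items, got {len(ia.answers)}"
            )

    for k, ia in enumerate(record.answers_6a):
        if ia.item_id != "6a":
            problems.append(f"answers_6a[{k}]: item_id field says {ia.item_id!r}")
        if len(ia.answers) != ITEM_SUBITEM_COUNTS["6a"]:
            problems.append(
                f"6a expects {ITEM_SUBITEM_COUNTS['6a']} sub-items, "
                f"got {len(ia.answers)} (outcome {k + 1})"
            )

    blinded = record.blinding is BlindingStatus.BLINDED
    for item in ("11a", "11b"):
        present = item in record.item_answers
        if present and not blinded:
            problems.append(
                f"item {item}: answers present but trial is not blinded "
                f"(status {record.blinding.value})"
            )
        if blinded and not present:
            problems.append(f"item {item}: answers required for a blinded trial")

    reg = record.registry
    if not reg.original_primary_outcomes and not reg.current_primary_outcomes:
        problems.append("registry: no registered primary outcome (original or current)")
    for i, spec in enumerate(reg.original_primary_outcomes):
        _validate_outcome(spec, f"registry.original_primary_outcomes[{i}]", problems)
    for i, spec in enumerate(reg.current_primary_outcomes):
        _validate_outcome(spec, f"registry.current_primary_outcomes[{i}]", problems)
    for i, spec in enumerate(record.article.primary_outcomes):
        _validate_outcome(spec, f"article.primary_outcomes[{i}]", problems)

    for i, res in enumerate(record.article.all_outcome_results):
        _validate_outcome(res.outcome, f"article.all_outcome_results[{i}].outcome", problems)
        if res.within_margin is not None and res.design is TrialDesign.SUPERIORITY:
            problems.append(
                f"article.all_outcome_results[{i}]: within_margin set for a "
                "superiority design"
            )

    tr = record.transparency
    no_statement = tr.sharing_statement is SharingStatement.NO_STATEMENT
    if no_statement != (tr.statement_location is Location.NONE):
        problems.append(
            "transparency: statement_location must be 'none' exactly when "
            "sharing_statement is 'no_statement'"
        )
    if not tr.protocol_available and tr.protocol_location is not Location.NONE:
        problems.append(
            "transparency: protocol_location set although protocol_available is false"
        )

    lat = record.latent
    if lat is not None:
        is_switch = lat.switch_category in SWITCH_CATEGORIES
        if is_switch != (lat.favorability is not None):
            problems.append(
                "latent: favorability must be present exactly for switch_* categories"
            )

    return problems
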