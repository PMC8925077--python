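"""Completeness scoring against the modified COBPeer checklist.

Each checklist item is answered as an ordered vector of yes/no/NA sub-item
answers. An item is *complete* when every assessable sub-item is reported,
*not reported* when none is, and *partial* in between; NA ("non-assessable")
answers are excluded from the denominator. The same three-case roll-up is
reused at every level: sub-items → item, per-outcome ratings → item 6a, item
ratings → overall trial rating.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .model import (
    Answer,
    ArticleInfo,
    BlindingStatus,
    ItemRating,
    OutcomeSpec,
    RegistryInfo,
    SCORED_ITEMS,
    TrialRecord,
)

__all__ = [
    "rate_item",
    "blend_ratings",
    "rate_item_6a",
    "rate_blinding",
    "select_primary_outcome",
    "PrimarySelection",
    "rate_trial_overall",
    "score_trial",
]


def rate_item(answers: Sequence[Answer]) -> ItemRating:
    """Roll an answer vector up to a three-level completeness rating.

    NA answers are removed from consideration; an all-NA vector rates
    not_applicable.
    """
    if len(answers) == 0:
        raise ValueError("cannot rate an empty answer vector")
    informative = [a for a in answers if a is not Answer.NA]
    if not informative:
        return ItemRating.NOT_APPLICABLE
    if all(a is Answer.YES for a in informative):
        return ItemRating.COMPLETE
    if all(a is Answer.NO for a in informative):
        return ItemRating.NOT_REPORTED
    return ItemRating.PARTIAL


def blend_ratings(ratings: Iterable[ItemRating]) -> ItemRating:
    """Apply the three-case rule to a collection of ratings.

    not_applicable ratings are excluded from the denominator, mirroring the
    NA-exclusion at sub-item level; all complete → complete, all
    not_reported → not_reported, otherwise partial.
    """
    applicable = [r for r in ratings if r is not ItemRating.NOT_APPLICABLE]
    if not applicable:
        return ItemRating.NOT_APPLICABLE
    if all(r is ItemRating.COMPLETE for r in applicable):
        return ItemRating.COMPLETE
    if all(r is ItemRating.NOT_REPORTED for r in applicable):
        return ItemRating.NOT_REPORTED
    return ItemRating.PARTIAL


def rate_item_6a(per_outcome_answers: Sequence[Sequence[Answer]]) -> ItemRating:
    """Rate the primary-outcome item for a trial with one answer vector per
    assessed primary outcome; per-outcome ratings blend with the same
    three-case rule (complete only if every outcome is complete)."""
    if len(per_outcome_answers) == 0:
        raise ValueError("item 6a needs at least one assessed primary outcome")
    return blend_ratings(rate_item(v) for v in per_outcome_answers)


def rate_blinding(
    status: BlindingStatus,
    answers_11a: Optional[Sequence[Answer]],
    answers_11b: Optional[Sequence[Answer]],
) -> ItemRating:
    """Rate the blinding item with its skip logic.

    Unblinded (or blinding-not-reported) trials skip items 11a/11b entirely
    and rate not_applicable. For blinded trials the 11a and 11b answers are
    rated together; the 11b sub-item (similarity of interventions) may be NA
    when irrelevant.
    """
    if status is not BlindingStatus.BLINDED:
        if answers_11a or answers_11b:
            raise ValueError(
                "items 11a/11b answered although the trial is not blinded"
            )
        return ItemRating.NOT_APPLICABLE
    if not answers_11a or not answers_11b:
        raise ValueError("blinded trial requires answers for items 11a and 11b")
    return rate_item(list(answers_11a) + list(answers_11b))


class PrimarySelection(NamedTuple):
    outcomes: list[OutcomeSpec]
    #: true when the article named no primary outcome and one was imputed
    imputed: bool


def select_primary_outcome(
    article: ArticleInfo, registry: RegistryInfo
) -> PrimarySelection:
    """Choose the outcome(s) assessed under item 6a.

    When the article clearly names its primary outcome(s), those are used.
    Otherwise one outcome is imputed, in fixed preference order: the outcome
    of the primary objective, then the outcome of the sample-size
    calculation, then the first registered primary outcome, then the first
    outcome with any result listed in the article.
    """
    if article.primary_clearly_identified:
        return PrimarySelection(list(article.primary_outcomes), False)
    if article.objective_outcome is not None:
        return PrimarySelection([article.objective_outcome], True)
    if article.sample_size_outcome is not None:
        return PrimarySelection([article.sample_size_outcome], True)
    registered = registry.original_primary_outcomes or registry.current_primary_outcomes
    if registered:
        return PrimarySelection([registered[0]], True)
    if article.all_outcome_results:
        return PrimarySelection([article.all_outcome_results[0].outcome], True)
    raise ValueError("no outcome available for item 6a")


def rate_trial_overall(item_ratings: Mapping[str, ItemRating]) -> ItemRating:
    """Blend per-item ratings into the overall trial rating.

    Expects one rating per scored item (6a, 8a, 9, 11, 13a, 13b, 17a, 19,
    23); "11" is the combined blinding rating, not_applicable for unblinded
    trials and hence excluded from the overall denominator.
    """
    missing = [k for k in SCORED_ITEMS if k not in item_ratings]
    if missing:
        raise ValueError(f"missing item ratings: {', '.join(missing)}")
    return blend_ratings(item_ratings[k] for k in SCORED_ITEMS)


def score_trial(record: TrialRecord) -> dict[str, ItemRating]:
    """Rate every checklist item of one record.

    Returns a mapping over :data:`SCORED_ITEMS`; feed it to
    :func:`rate_trial_overall` for the trial-level verdict.
    """
    ratings: dict[str, ItemRating] = {}
    ratings["6a"] = rate_item_6a([ia.answers for ia in record.answers_6a])
    a11a = record.item_answers.get("11a")
    a11b = record.item_answers.get("11b")
    ratings["11"] = rate_blinding(
        record.blinding,
        a11a.answers if a11a else None,
        a11b.answers if a11b else None,
    )
    for item in ("8a", "9", "13a", "13b", "17a", "19", "23"):
        try:
            ratings[item] = rate_item(record.item_answers[item].answers)
        except KeyError:
            raise ValueError(
                f"trial {record.trial_id!r}: no answers for item {item}"
            ) from None
    return ratings
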