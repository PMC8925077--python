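"""Does a primary-outcome switch favor statistically significant results?

Significance is read off the published result: p < 0.05 for superiority
designs, the pre-set margin criterion for equivalence/non-inferiority
designs, *unclear* when neither is available. A switch favors significance
when (a) a new statistically significant efficacy primary outcome was
introduced, (b) a non-significant efficacy primary outcome was omitted or
demoted to secondary, or (c) a new, statistically non-significant safety
primary outcome was introduced (e.g. the experimental arm showed no excess
harm although the trial was not powered for that comparison). Every other
assessable discrepancy does not favor significance. When the article
reports no result for an outcome involved in the discrepancy, the verdict
is non-assessable.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

from .model import (
    Favorability,
    OutcomeResult,
    OutcomeSpec,
    OutcomeType,
    SWITCH_CATEGORIES,
    SignificanceClass,
    SwitchCategory,
    TrialDesign,
    TriggerRule,
)
from .switching import MatchSet

__all__ = ["classify_significance", "FavorabilityVerdict", "assess_favorability"]

ALPHA = 0.05


def classify_significance(result: OutcomeResult) -> SignificanceClass:
    """Classify one published result as significant / non-significant /
    unclear, using the margin criterion instead of the p-value for
    equivalence and non-inferiority designs."""
    if not result.summary_reported:
        return SignificanceClass.UNCLEAR
    if result.design is TrialDesign.SUPERIORITY:
        if result.p_value is None:
            return SignificanceClass.UNCLEAR
        return (
            SignificanceClass.SIGNIFICANT
            if result.p_value < ALPHA
            else SignificanceClass.NON_SIGNIFICANT
        )
    if result.within_margin is None:
        return SignificanceClass.UNCLEAR
    return (
        SignificanceClass.SIGNIFICANT
        if result.within_margin
        else SignificanceClass.NON_SIGNIFICANT
    )


class FavorabilityVerdict(NamedTuple):
    value: Favorability
    trigger: TriggerRule


def _find_significance(
    spec: OutcomeSpec, results: Sequence[OutcomeResult]
) -> SignificanceClass:
    """Significance of the published result for ``spec``, matched on the
    normalized variable label; unclear when the article reports none."""
    target = spec.variable_normalized
    for res in results:
        if res.outcome.variable_normalized == target:
            return classify_significance(res)
    return SignificanceClass.UNCLEAR


def assess_favorability(
    category: SwitchCategory,
    match: MatchSet,
    results: Sequence[OutcomeResult],
) -> FavorabilityVerdict:
    """Decide whether a detected switch favored significant results.

    ``results`` is the article's full result list (primary and secondary),
    which is where a demoted registered primary's result is found. The
    outcomes *involved* in the discrepancy — introduced article primaries,
    removed/demoted registered primaries, and matched pairs whose definition
    changed — must all have an assessable result; otherwise the verdict is
    non-assessable. Any single positive trigger makes the trial favor
    significance.
    """
    if category not in SWITCH_CATEGORIES:
        raise ValueError(
            f"favorability is defined only for switch categories, got {category.value}"
        )

    involved: list[tuple[OutcomeSpec, SignificanceClass, Optional[TriggerRule]]] = []
    for spec in match.unmatched_article:  # introduced primaries
        sig = _find_significance(spec, results)
        trigger: Optional[TriggerRule] = None
        if spec.outcome_type is OutcomeType.EFFICACY:
            if sig is SignificanceClass.SIGNIFICANT:
                trigger = TriggerRule.A
        else:
            if sig is SignificanceClass.NON_SIGNIFICANT:
                trigger = TriggerRule.C
        involved.append((spec, sig, trigger))
    for spec in match.unmatched_registered:  # omitted or demoted primaries
        sig = _find_significance(spec, results)
        trigger = None
        if (
            spec.outcome_type is OutcomeType.EFFICACY
            and sig is SignificanceClass.NON_SIGNIFICANT
        ):
            trigger = TriggerRule.B
        involved.append((spec, sig, trigger))
    for pair in match.matched_pairs:  # definition changes
        if pair.changed_fields:
            sig = _find_significance(pair.article, results)
            involved.append((pair.article, sig, None))

    if any(sig is SignificanceClass.UNCLEAR for _, sig, _ in involved):
        return FavorabilityVerdict(Favorability.NON_ASSESSABLE, TriggerRule.NONE)
    for _, _, trigger in involved:
        if trigger is not None:
            return FavorabilityVerdict(Favorability.FAVORS_SIGNIFICANCE, trigger)
    return FavorabilityVerdict(Favorability.DOES_NOT_FAVOR, TriggerRule.NONE)
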