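"""Seeded synthetic cohorts of internally consistent trial records.

Generation is *label-first*: each trial's verdicts (item completeness
ratings, blinding status, retrospective flag, switch category and subtype,
favorability and its triggering rule, transparency flags) are drawn from
configurable prevalences, and raw fields — sub-item answer vectors,
registered and published outcome lists, p-values, dates — are then
materialized so that the rules engine reproduces every latent label
exactly. This makes round-trip testing exact and lets every pipeline stage
run without downloading any registry data.

The shipped :data:`PAPER_PREVALENCES` configuration emulates a cohort of
101 randomized controlled trials in colorectal cancer with the published
indicator prevalences (5/101 fully complete, 49/101 retrospectively
registered, 23/101 with primary-outcome switching, and so on).

Several indicators are logically entangled, so they are sampled jointly
from conditional distributions calibrated to preserve the configured
marginals (details in the methods note):

* overall completeness is drawn first; a fully complete trial forces every
  item rating to *complete*, and item ratings of other trials are drawn
  from the complementary conditional distributions;
* a trial whose article names no clear primary outcome is both
  switch-non-assessable and at best *partial* on the primary-outcome item
  (its first sub-item is answered "no");
* a favoring switch is infeasible for definition-only switches under the
  stated favorability rules, so the favor probability is reweighted within
  the eligible subtypes.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import (
    Answer,
    ArticleInfo,
    BlindingStatus,
    ITEM_SUBITEM_COUNTS,
    Direction,
    Favorability,
    ItemAnswers,
    ItemRating,
    LatentLabels,
    Location,
    OutcomeResult,
    OutcomeRole,
    OutcomeSource,
    OutcomeSpec,
    OutcomeType,
    RegistryInfo,
    SCORED_ITEMS,
    SharingStatement,
    SwitchCategory,
    TransparencyInfo,
    TrialRecord,
    TriggerRule,
)
from .report import CohortSummary, TrialVerdicts, summarize_cohort, summarize_rows
from .scoring import blend_ratings
from .transparency import summarize_transparency

__all__ = [
    "GeneratorConfig",
    "PAPER_PREVALENCES",
    "generate_cohort",
    "summary_from_latents",
    "estimate_prevalence_recovery",
]

_EPS = 1e-9


def _check_cat(d: dict[str, float], keys: tuple[str, ...], name: str) -> None:
    if set(d) != set(keys):
        raise ValueError(f"{name}: expected keys {keys}, got {tuple(d)}")
    if any(not 0.0 <= v <= 1.0 for v in d.values()):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(d.values()) - 1.0) > _EPS:
        raise ValueError(f"{name}: probabilities sum to {sum(d.values())}, not 1")


class GeneratorConfig(BaseModel):
    """Cohort size, seed and per-indicator prevalence vectors.

    Three-level item blocks are ``{complete, partial, not_reported}``
    marginal probabilities; conditional probabilities (e.g. the favor rate
    among assessable switch trials) are stated over their own denominator,
    mirroring the nested denominators of the audited table.
    """

    n: int = Field(default=101, ge=1)
    seed: int = 0

    overall_complete: float = Field(default=5 / 101, ge=0.0, le=1.0)

    item_6a: dict[str, float] = Field(
        default_factory=lambda: {"complete": 74 / 101, "partial": 27 / 101,
                                 "not_reported": 0.0}
    )
    participant_flow: dict[str, float] = Field(
        default_factory=lambda: {"complete": 81 / 101, "partial": 19 / 101,
                                 "not_reported": 1 / 101}
    )
    primary_results: dict[str, float] = Field(
        default_factory=lambda: {"complete": 55 / 101, "partial": 42 / 101,
                                 "not_reported": 4 / 101}
    )
    harms: dict[str, float] = Field(
        default_factory=lambda: {"complete": 13 / 101, "partial": 49 / 101,
                                 "not_reported": 39 / 101}
    )
    sequence_generation_complete: float = Field(default=73 / 101, ge=0.0, le=1.0)
    allocation_concealment_complete: float = Field(default=53 / 101, ge=0.0, le=1.0)
    registration_number_complete: float = Field(default=90 / 101, ge=0.0, le=1.0)

    blinding: dict[str, float] = Field(
        default_factory=lambda: {"blinded": 47 / 101, "unblinded": 47 / 101,
                                 "not_reported": 7 / 101}
    )
    blinding_complete_given_blinded: float = Field(default=32 / 47, ge=0.0, le=1.0)
    flow_chart_available: float = Field(default=94 / 101, ge=0.0, le=1.0)

    retrospective: float = Field(default=49 / 101, ge=0.0, le=1.0)
    switch_block: dict[str, float] = Field(
        default_factory=lambda: {"non_assessable": 12 / 101, "imprecise": 3 / 101,
                                 "no_switch": 63 / 101, "switched": 23 / 101}
    )
    switch_subtype: dict[str, float] = Field(
        default_factory=lambda: {"add_remove": 10 / 23, "definition": 5 / 23,
                                 "combination": 8 / 23}
    )
    assessable_given_switched: float = Field(default=16 / 23, ge=0.0, le=1.0)
    favors_given_assessable: float = Field(default=6 / 16, ge=0.0, le=1.0)
    justified_given_switched: float = Field(default=0.0, ge=0.0, le=1.0)

    protocol_available: float = Field(default=34 / 101, ge=0.0, le=1.0)
    protocol_location: dict[str, float] = Field(
        default_factory=lambda: {"publication": 20 / 34, "registry": 8 / 34,
                                 "both": 6 / 34}
    )
    protocol_complete_given_available: float = Field(default=29 / 34, ge=0.0, le=1.0)
    sap_available: float = Field(default=32 / 101, ge=0.0, le=1.0)
    sharing: dict[str, float] = Field(
        default_factory=lambda: {"willing": 25 / 101, "not_willing": 25 / 101,
                                 "no_statement": 51 / 101}
    )
    statement_location: dict[str, float] = Field(
        default_factory=lambda: {"publication": 19 / 25, "registry": 5 / 25,
                                 "both": 1 / 25}
    )
    access_location_given: float = Field(default=22 / 25, ge=0.0, le=1.0)
    timeframe_given: float = Field(default=6 / 25, ge=0.0, le=1.0)
    researchers_only: float = Field(default=8 / 25, ge=0.0, le=1.0)
    other_restrictions: float = Field(default=14 / 25, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        three = ("complete", "partial", "not_reported")
        _check_cat(self.item_6a, three, "item_6a")
        _check_cat(self.participant_flow, three, "participant_flow")
        _check_cat(self.primary_results, three, "primary_results")
        _check_cat(self.harms, three, "harms")
        _check_cat(self.blinding, ("blinded", "unblinded", "not_reported"), "blinding")
        _check_cat(
            self.switch_block,
            ("non_assessable", "imprecise", "no_switch", "switched"),
            "switch_block",
        )
        _check_cat(
            self.switch_subtype,
            ("add_remove", "definition", "combination"),
            "switch_subtype",
        )
        _check_cat(
            self.protocol_location, ("publication", "registry", "both"),
            "protocol_location",
        )
        _check_cat(
            self.sharing, ("willing", "not_willing", "no_statement"), "sharing"
        )
        _check_cat(
            self.statement_location, ("publication", "registry", "both"),
            "statement_location",
        )
        pc = self.overall_complete
        for name, p in [
            ("item_6a", self.item_6a["complete"]),
            ("participant_flow", self.participant_flow["complete"]),
            ("primary_results", self.primary_results["complete"]),
            ("harms", self.harms["complete"]),
            ("sequence_generation_complete", self.sequence_generation_complete),
            ("allocation_concealment_complete", self.allocation_concealment_complete),
            ("registration_number_complete", self.registration_number_complete),
            ("blinding_complete_given_blinded", self.blinding_complete_given_blinded),
        ]:
            if p < pc - _EPS:
                raise ValueError(
                    f"{name}: complete marginal {p} below overall_complete {pc}"
                )
        if self.item_6a["partial"] < self.switch_block["non_assessable"] - _EPS:
            raise ValueError(
                "item_6a partial marginal must cover the switch-non-assessable "
                "mass (no clear article primary outcome forces a partial rating)"
            )
        p_def = self.switch_subtype["definition"]
        if self.favors_given_assessable > (1.0 - p_def) + _EPS:
            raise ValueError(
                "favors_given_assessable exceeds the probability mass of switch "
                "subtypes able to realize a favoring discrepancy"
            )
        return self


#: Prevalences of the audited cohort of 101 colorectal-cancer RCTs. The four
#: switch blocks are 12/3/63/23: the published counts print 66 trials with
#: no switch, but 12+3+66+23 = 104 > 101, so the no-switch count is reduced
#: to 63 to restore the partition (the three other counts carry their own
#: within-block percentages and are kept).
PAPER_PREVALENCES = GeneratorConfig()


def _draw(rng: np.random.Generator, dist: dict[str, float]) -> str:
    u = rng.random()
    acc = 0.0
    keys = list(dist)
    for k in keys:
        acc += dist[k]
        if u < acc:
            return k
    return keys[-1]


def _coin(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _cond_three(block: dict[str, float], pc: float) -> dict[str, float]:
    """Three-level distribution conditional on the trial not being overall
    complete, preserving the configured marginals."""
    rest = 1.0 - pc
    return {
        "complete": max((block["complete"] - pc) / rest, 0.0),
        "partial": block["partial"] / rest,
        "not_reported": block["not_reported"] / rest,
    }


def _vector(rng: np.random.Generator, rating: str, k: int) -> list[Answer]:
    if rating == "complete":
        return [Answer.YES] * k
    if rating == "not_reported":
        return [Answer.NO] * k
    if k < 2:
        raise ValueError("a single-sub-item answer vector cannot be partial")
    answers = [Answer.YES] * k
    answers[int(rng.integers(k))] = Answer.NO
    return answers


_RATING = {
    "complete": ItemRating.COMPLETE,
    "partial": ItemRating.PARTIAL,
    "not_reported": ItemRating.NOT_REPORTED,
}


def _spec(
    variable: str,
    *,
    time_frame: str = "6 months",
    metric: str = "final value",
    role: OutcomeRole = OutcomeRole.PRIMARY,
    outcome_type: OutcomeType = OutcomeType.EFFICACY,
    source: OutcomeSource = OutcomeSource.ARTICLE,
) -> OutcomeSpec:
    return OutcomeSpec(
        variable=variable,
        assessment_method="synthetic assessment",
        analysis_metric=metric,
        time_frame=time_frame,
        role=role,
        outcome_type=outcome_type,
        source=source,
    )


def _result(
    rng: np.random.Generator,
    spec: OutcomeSpec,
    significance: Optional[bool],
) -> OutcomeResult:
    """A superiority-design result: significant, non-significant, or (None)
    unreported."""
    if significance is None:
        return OutcomeResult(
            outcome=spec, p_value=None, direction=Direction.UNCLEAR,
            summary_reported=False,
        )
    p = rng.uniform(0.001, 0.049) if significance else rng.uniform(0.06, 0.95)
    return OutcomeResult(
        outcome=spec,
        p_value=float(p),
        direction=(
            Direction.SUPPORTS_INTERVENTION if significance else Direction.UNCLEAR
        ),
        summary_reported=True,
    )


def _dates(rng: np.random.Generator, retrospective: bool) -> tuple[str, str]:
    start = _dt.date(
        int(rng.integers(2008, 2019)), int(rng.integers(1, 13)), int(rng.integers(1, 29))
    )
    if retrospective:
        # offset > 31 days keeps the verdict stable under month-precision
        reg = start + _dt.timedelta(days=int(rng.integers(40, 700)))
    else:
        reg = start - _dt.timedelta(days=int(rng.integers(10, 400)))

    def fmt(d: _dt.date) -> str:
        if rng.random() < 0.15:  # month-precision, as in many registry exports
            return f"{d.year:04d}-{d.month:02d}"
        return d.isoformat()

    return fmt(reg), fmt(start)


def _materialize_outcomes(
    rng: np.random.Generator,
    category: SwitchCategory,
    subtype: Optional[str],
    favorability: Optional[Favorability],
    trigger: Optional[TriggerRule],
) -> tuple[RegistryInfo, list[OutcomeSpec], list[OutcomeResult], bool, Optional[OutcomeSpec]]:
    """Registered/published outcome lists and article results realizing the
    latent switch and favorability labels.

    Returns (registry info without dates, article primary outcomes, article
    results, primary_clearly_identified, objective fallback outcome).
    """
    reg_kw = dict(source=OutcomeSource.REGISTRY_ORIGINAL)
    art_kw = dict(source=OutcomeSource.ARTICLE)
    p1_reg = _spec("outcome-1", **reg_kw)
    p1_art = _spec("outcome-1", **art_kw)
    registry = RegistryInfo(original_primary_outcomes=[p1_reg])
    results: list[OutcomeResult] = []
    favors = favorability is Favorability.FAVORS_SIGNIFICANCE
    unassessable = favorability is Favorability.NON_ASSESSABLE

    if category is SwitchCategory.NON_ASSESSABLE:
        results.append(_result(rng, p1_art, _coin(rng, 0.5)))
        return registry, [], results, False, p1_art

    if category is SwitchCategory.IMPRECISE_REGISTRATION:
        registry = RegistryInfo(
            original_primary_outcomes=[
                _spec("clinical outcomes (unspecified)", time_frame="unspecified",
                      metric="unspecified", **reg_kw)
            ],
            imprecise_registration=True,
        )
        results.append(_result(rng, p1_art, _coin(rng, 0.5)))
        return registry, [p1_art], results, True, None

    if category is SwitchCategory.NO_SWITCH:
        results.append(_result(rng, p1_art, _coin(rng, 0.5)))
        return registry, [p1_art], results, True, None

    # switch trials --------------------------------------------------------
    changed = subtype in ("definition", "combination")
    if changed:
        p1_art = _spec("outcome-1", time_frame="12 months", **art_kw)
    article = [p1_art]
    results.append(_result(rng, p1_art, None if (
        unassessable and subtype == "definition") else _coin(rng, 0.5)))

    if subtype == "definition":
        return registry, article, results, True, None

    # add/remove component (alone or combined with the definition change)
    if favors and trigger in (TriggerRule.A, TriggerRule.C):
        otype = OutcomeType.EFFICACY if trigger is TriggerRule.A else OutcomeType.SAFETY
        new = _spec("outcome-2", outcome_type=otype, **art_kw)
        article.append(new)
        results.append(_result(rng, new, trigger is TriggerRule.A))
    elif favors and trigger is TriggerRule.B:
        removed = _spec("outcome-2", **reg_kw)
        registry = RegistryInfo(original_primary_outcomes=[p1_reg, removed])
        demoted = _spec("outcome-2", role=OutcomeRole.SECONDARY, **art_kw)
        results.append(_result(rng, demoted, False))
    elif unassessable:
        if subtype == "add_remove":
            new = _spec("outcome-2", **art_kw)
            article.append(new)
            results.append(_result(rng, new, None))
        else:  # combination: the removed outcome has no article result at all
            removed = _spec("outcome-2", **reg_kw)
            registry = RegistryInfo(original_primary_outcomes=[p1_reg, removed])
    else:  # does_not_favor
        if subtype == "add_remove":
            new = _spec("outcome-2", **art_kw)  # introduced but non-significant
            article.append(new)
            results.append(_result(rng, new, False))
        else:  # combination: removed outcome was significant
            removed = _spec("outcome-2", **reg_kw)
            registry = RegistryInfo(original_primary_outcomes=[p1_reg, removed])
            demoted = _spec("outcome-2", role=OutcomeRole.SECONDARY, **art_kw)
            results.append(_result(rng, demoted, True))
    return registry, article, results, True, None


_CATEGORY = {
    "non_assessable": SwitchCategory.NON_ASSESSABLE,
    "imprecise": SwitchCategory.IMPRECISE_REGISTRATION,
    "no_switch": SwitchCategory.NO_SWITCH,
    "add_remove": SwitchCategory.SWITCH_ADD_REMOVE,
    "definition": SwitchCategory.SWITCH_DEFINITION,
    "combination": SwitchCategory.SWITCH_COMBINATION,
}


def _sample_item_labels(
    rng: np.random.Generator, config: GeneratorConfig, overall_complete: bool,
    block_key: str, blinding: BlindingStatus,
) -> dict[str, str]:
    """Draw per-item rating labels consistent with the overall-completeness
    and switch-block draws (see module docstring for the conditioning)."""
    pc = config.overall_complete
    blinded = blinding is BlindingStatus.BLINDED
    if overall_complete:
        labels = {k: "complete" for k in
                  ("6a", "8a", "9", "13a_13b", "17a", "19", "23")}
        labels["11"] = "complete" if blinded else "not_applicable"
        return labels

    p_na = config.switch_block["non_assessable"]
    rest = 1.0 - pc - p_na
    if block_key == "non_assessable" or rest <= 0.0:
        cond_6a = None  # forced partial: the article names no clear primary
    else:
        cond_6a = {
            "complete": max((config.item_6a["complete"] - pc) / rest, 0.0),
            "partial": max((config.item_6a["partial"] - p_na) / rest, 0.0),
            "not_reported": config.item_6a["not_reported"] / rest,
        }
    q_blind = (
        (config.blinding_complete_given_blinded - pc) / (1.0 - pc)
        if blinded
        else None
    )

    for _ in range(10_000):
        labels = {
            "6a": "partial" if cond_6a is None else _draw(rng, cond_6a),
            "8a": "complete"
            if _coin(rng, (config.sequence_generation_complete - pc) / (1.0 - pc))
            else "not_reported",
            "9": "complete"
            if _coin(rng, (config.allocation_concealment_complete - pc) / (1.0 - pc))
            else "not_reported",
            "11": (
                ("complete" if _coin(rng, q_blind) else "partial")
                if blinded
                else "not_applicable"
            ),
            "13a_13b": _draw(rng, _cond_three(config.participant_flow, pc)),
            "17a": _draw(rng, _cond_three(config.primary_results, pc)),
            "19": _draw(rng, _cond_three(config.harms, pc)),
            "23": "complete"
            if _coin(rng, (config.registration_number_complete - pc) / (1.0 - pc))
            else "not_reported",
        }
        applicable = [v for v in labels.values() if v != "not_applicable"]
        if not all(v == "complete" for v in applicable):
            return labels
    raise ValueError(
        "infeasible label combination: item prevalences leave no probability "
        "mass for a not-fully-complete trial"
    )


def _make_record(
    rng: np.random.Generator, config: GeneratorConfig, trial_id: str
) -> TrialRecord:
    overall_complete = _coin(rng, config.overall_complete)
    blinding = BlindingStatus(_draw(rng, config.blinding))

    # switch block, conditioned on overall completeness (a fully complete
    # trial has a clearly identified primary outcome)
    p_na = config.switch_block["non_assessable"]
    non_na = {k: v / (1.0 - p_na) for k, v in config.switch_block.items()
              if k != "non_assessable"}
    if overall_complete:
        block_key = _draw(rng, non_na)
    else:
        pc = config.overall_complete
        if _coin(rng, p_na / (1.0 - pc)):
            block_key = "non_assessable"
        else:
            block_key = _draw(rng, non_na)

    item_labels = _sample_item_labels(rng, config, overall_complete, block_key, blinding)

    # --- switch / favorability latents ------------------------------------
    subtype: Optional[str] = None
    favorability: Optional[Favorability] = None
    trigger: Optional[TriggerRule] = None
    if block_key == "switched":
        subtype = _draw(rng, config.switch_subtype)
        if _coin(rng, config.assessable_given_switched):
            p_def = config.switch_subtype["definition"]
            p_eligible = 1.0 - p_def
            p_favor = (
                config.favors_given_assessable / p_eligible if p_eligible > 0 else 0.0
            )
            if subtype == "definition":
                favorability = Favorability.DOES_NOT_FAVOR
                trigger = TriggerRule.NONE
            elif _coin(rng, p_favor):
                favorability = Favorability.FAVORS_SIGNIFICANCE
                trigger = TriggerRule(_draw(rng, {"a": 0.4, "b": 0.4, "c": 0.2}))
            else:
                favorability = Favorability.DOES_NOT_FAVOR
                trigger = TriggerRule.NONE
        else:
            favorability = Favorability.NON_ASSESSABLE
            trigger = TriggerRule.NONE
    category = _CATEGORY[subtype if block_key == "switched" else block_key]

    registry, article_primaries, results, clearly_identified, objective = (
        _materialize_outcomes(rng, category, subtype, favorability, trigger)
    )

    retrospective = _coin(rng, config.retrospective)
    reg_date, start_date = _dates(rng, retrospective)
    registry = registry.model_copy(
        update={"registration_date": reg_date, "start_date": start_date}
    )

    # --- answer vectors ----------------------------------------------------
    item_answers: dict[str, ItemAnswers] = {}
    flow_label = item_labels.pop("13a_13b")
    if flow_label == "partial":
        lab_13a, lab_13b = ("complete", "partial") if _coin(rng, 0.5) else (
            "partial", "complete")
    else:
        lab_13a = lab_13b = flow_label
    per_item = {
        "8a": item_labels["8a"], "9": item_labels["9"], "13a": lab_13a,
        "13b": lab_13b, "17a": item_labels["17a"], "19": item_labels["19"],
        "23": item_labels["23"],
    }
    for item, label in per_item.items():
        item_answers[item] = ItemAnswers(
            item_id=item,
            answers=_vector(rng, label, ITEM_SUBITEM_COUNTS[item]),
        )
    if blinding is BlindingStatus.BLINDED:
        if item_labels["11"] == "complete":
            a11a, a11b = [Answer.YES, Answer.YES], [
                Answer.NA if _coin(rng, 0.3) else Answer.YES
            ]
        else:
            a11a, a11b = [Answer.YES, Answer.NO], [Answer.YES]
        item_answers["11a"] = ItemAnswers(item_id="11a", answers=a11a)
        item_answers["11b"] = ItemAnswers(item_id="11b", answers=a11b)

    label_6a = item_labels["6a"]
    n_vectors = max(len(article_primaries), 1)
    vectors_6a: list[list[Answer]] = []
    for j in range(n_vectors):
        if label_6a == "complete":
            vec = [Answer.YES] * 7
        elif label_6a == "not_reported":
            vec = [Answer.NO] * 7
        elif not clearly_identified:
            vec = [Answer.NO] + [Answer.YES] * 6
        elif j == 0:
            vec = [Answer.YES] * 7
            vec[1 + int(rng.integers(6))] = Answer.NO
        else:
            vec = [Answer.YES] * 7
        vectors_6a.append(vec)

    # --- latent labels and assembled record --------------------------------
    ratings = {
        "6a": _RATING[label_6a],
        "8a": _RATING[per_item["8a"]],
        "9": _RATING[per_item["9"]],
        "11": (
            _RATING[item_labels["11"]]
            if blinding is BlindingStatus.BLINDED
            else ItemRating.NOT_APPLICABLE
        ),
        "13a": _RATING[lab_13a],
        "13b": _RATING[lab_13b],
        "17a": _RATING[per_item["17a"]],
        "19": _RATING[per_item["19"]],
        "23": _RATING[per_item["23"]],
    }
    latent = LatentLabels(
        item_ratings=ratings,
        overall=blend_ratings(ratings[k] for k in SCORED_ITEMS),
        blinding=blinding,
        retrospective=retrospective,
        switch_category=category,
        favorability=favorability,
        trigger_rule=trigger,
    )

    # --- transparency -------------------------------------------------------
    protocol_available = _coin(rng, config.protocol_available)
    sharing = SharingStatement(_draw(rng, config.sharing))
    has_statement = sharing is not SharingStatement.NO_STATEMENT
    statement_location = (
        Location(_draw(rng, config.statement_location)) if has_statement
        else Location.NONE
    )
    willing = sharing is SharingStatement.WILLING
    transparency = TransparencyInfo(
        protocol_available=protocol_available,
        protocol_location=(
            Location(_draw(rng, config.protocol_location)) if protocol_available
            else Location.NONE
        ),
        protocol_complete=(
            _coin(rng, config.protocol_complete_given_available)
            if protocol_available else None
        ),
        protocol_in_english=True if protocol_available else None,
        sap_available=_coin(rng, config.sap_available),
        sharing_statement=sharing,
        statement_location=statement_location,
        access_location_given=willing and _coin(rng, config.access_location_given),
        timeframe_given=willing and _coin(rng, config.timeframe_given),
        researchers_only=willing and _coin(rng, config.researchers_only),
        other_restrictions=willing and _coin(rng, config.other_restrictions),
        registry_publication_consistent=(
            True if statement_location is Location.BOTH else None
        ),
    )

    article = ArticleInfo(
        primary_clearly_identified=clearly_identified,
        primary_outcomes=article_primaries,
        all_outcome_results=results,
        objective_outcome=objective,
        sample_size_outcome=None,
        registration_number_reported=per_item["23"] == "complete",
        switch_justified=(
            block_key == "switched" and _coin(rng, config.justified_given_switched)
        ),
        flow_chart_reported=_coin(rng, config.flow_chart_available),
    )

    return TrialRecord(
        trial_id=trial_id,
        item_answers=item_answers,
        answers_6a=[ItemAnswers(item_id="6a", answers=v) for v in vectors_6a],
        blinding=blinding,
        registry=registry,
        article=article,
        transparency=transparency,
        latent=latent,
    )


def generate_cohort(
    config: GeneratorConfig, seed: Optional[int] = None
) -> list[TrialRecord]:
    """Generate ``config.n`` internally consistent records; ``seed``
    overrides ``config.seed``. Records carry their latent labels."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [_make_record(rng, config, f"trial-{i + 1:04d}") for i in range(config.n)]


def summary_from_latents(records: Sequence[TrialRecord]) -> CohortSummary:
    """Cohort summary tallied directly from latent labels — the independent
    side of the generator round-trip check."""
    rows = []
    for rec in records:
        lat = rec.latent
        if lat is None:
            raise ValueError(f"record {rec.trial_id} carries no latent labels")
        rows.append(
            TrialVerdicts(
                trial_id=rec.trial_id,
                ratings=lat.item_ratings,
                overall=lat.overall,
                flow_combined=blend_ratings(
                    [lat.item_ratings["13a"], lat.item_ratings["13b"]]
                ),
                blinding=lat.blinding,
                flow_chart=rec.article.flow_chart_reported,
                registration_number=rec.article.registration_number_reported,
                retrospective=lat.retrospective,
                switch_category=lat.switch_category,
                favorability=lat.favorability,
                trigger=lat.trigger_rule,
                switch_justified=rec.article.switch_justified,
                transparency=summarize_transparency(rec),
            )
        )
    return summarize_rows(rows)


def estimate_prevalence_recovery(
    config: GeneratorConfig, reps: int, base_seed: int
) -> dict[str, float]:
    """Mean of every indicator's proportion over ``reps`` cohorts generated
    with seeds ``base_seed .. base_seed + reps - 1``, each run through the
    full pipeline (:func:`summarize_cohort`)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    totals: dict[str, float] = {}
    for i in range(reps):
        cohort = generate_cohort(config, seed=base_seed + i)
        fractions = summarize_cohort(cohort).fractions()
        for key, value in fractions.items():
            totals[key] = totals.get(key, 0.0) + value
    return {key: value / reps for key, value in totals.items()}
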