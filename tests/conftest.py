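import pytest

from trialaudit.model import (
    Answer,
    ArticleInfo,
    BlindingStatus,
    ITEM_SUBITEM_COUNTS,
    ItemAnswers,
    Location,
    OutcomeRole,
    OutcomeSource,
    OutcomeSpec,
    OutcomeResult,
    RegistryInfo,
    SharingStatement,
    TransparencyInfo,
    TrialRecord,
)

Y, N, NA = Answer.YES, Answer.NO, Answer.NA


def outcome(
    variable="overall survival",
    time_frame="3 years",
    metric="time to event",
    role=OutcomeRole.PRIMARY,
    outcome_type="efficacy",
    source=OutcomeSource.ARTICLE,
):
    return OutcomeSpec(
        variable=variable,
        analysis_metric=metric,
        time_frame=time_frame,
        role=role,
        outcome_type=outcome_type,
        source=source,
    )


def result(spec, p=0.2, reported=True):
    return OutcomeResult(
        outcome=spec, p_value=p if reported else None, summary_reported=reported
    )


def make_record(
    trial_id="t-1",
    blinding=BlindingStatus.UNBLINDED,
    registered=None,
    published=None,
    results=None,
    clearly_identified=True,
    imprecise=False,
    registration_date="2014-06-01",
    start_date="2015-01-10",
    answers=None,
    **article_kw,
):
    """A fully consistent record: all items answered 'yes', one registered
    primary outcome republished unchanged, prospective registration."""
    reg_out = outcome(source=OutcomeSource.REGISTRY_ORIGINAL)
    registered = [reg_out] if registered is None else registered
    published = [outcome()] if published is None else published
    results = [result(o) for o in published] if results is None else results
    item_answers = {
        item: ItemAnswers(item_id=item, answers=[Y] * ITEM_SUBITEM_COUNTS[item])
        for item in ("8a", "9", "13a", "13b", "17a", "19", "23")
    }
    if blinding is BlindingStatus.BLINDED:
        item_answers["11a"] = ItemAnswers(item_id="11a", answers=[Y, Y])
        item_answers["11b"] = ItemAnswers(item_id="11b", answers=[Y])
    if answers:
        item_answers.update(answers)
    return TrialRecord(
        trial_id=trial_id,
        item_answers=item_answers,
        answers_6a=[ItemAnswers(item_id="6a", answers=[Y] * 7)],
        blinding=blinding,
        registry=RegistryInfo(
            registration_date=registration_date,
            start_date=start_date,
            original_primary_outcomes=registered,
            imprecise_registration=imprecise,
        ),
        article=ArticleInfo(
            primary_clearly_identified=clearly_identified,
            primary_outcomes=published,
            all_outcome_results=results,
            registration_number_reported=True,
            **article_kw,
        ),
        transparency=TransparencyInfo(
            sharing_statement=SharingStatement.WILLING,
            statement_location=Location.PUBLICATION,
        ),
    )


@pytest.fixture(scope="session")
def paper_cohort():
    from trialaudit.simulate import PAPER_PREVALENCES, generate_cohort

    return generate_cohort(PAPER_PREVALENCES, seed=7)
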