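"""Significance classification and the switch-favorability rules."""

import pytest

from trialaudit.favorability import assess_favorability, classify_significance
from trialaudit.model import (
    Favorability,
    OutcomeResult,
    OutcomeRole,
    OutcomeSource,
    SignificanceClass,
    SwitchCategory,
    TrialDesign,
    TriggerRule,
)
from trialaudit.switching import match_outcomes

from conftest import outcome, result

REG = OutcomeSource.REGISTRY_ORIGINAL
AR = SwitchCategory.SWITCH_ADD_REMOVE


class TestClassifySignificance:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.049, SignificanceClass.SIGNIFICANT),
            (0.05, SignificanceClass.NON_SIGNIFICANT),  # threshold is strict
            (None, SignificanceClass.UNCLEAR),
        ],
    )
    def test_superiority_p_value_rule(self, p, expected):
        res = OutcomeResult(outcome=outcome(), p_value=p, summary_reported=p is not None)
        assert classify_significance(res) is expected

    @pytest.mark.parametrize(
        "within,expected",
        [
            (True, SignificanceClass.SIGNIFICANT),
            (False, SignificanceClass.NON_SIGNIFICANT),
            (None, SignificanceClass.UNCLEAR),
        ],
    )
    def test_margin_rule_for_non_inferiority(self, within, expected):
        res = OutcomeResult(
            outcome=outcome(),
            design=TrialDesign.NON_INFERIORITY,
            within_margin=within,
        )
        assert classify_significance(res) is expected

    def test_unreported_result_is_unclear_even_with_p(self):
        res = OutcomeResult(outcome=outcome(), p_value=0.01, summary_reported=False)
        assert classify_significance(res) is SignificanceClass.UNCLEAR


def _assess(registered, published, results, category=AR):
    match = match_outcomes(registered, published)
    return assess_favorability(category, match, results)


class TestAssessFavorability:
    def test_new_significant_efficacy_primary_favors(self):
        new = outcome("ORR")
        verdict = _assess(
            [outcome("OS", source=REG)],
            [outcome("OS"), new],
            [result(outcome("OS"), p=0.3), result(new, p=0.01)],
        )
        assert verdict.value is Favorability.FAVORS_SIGNIFICANCE
        assert verdict.trigger is TriggerRule.A

    def test_demoted_non_significant_efficacy_primary_favors(self):
        demoted = outcome("ORR", role=OutcomeRole.SECONDARY)
        verdict = _assess(
            [outcome("OS", source=REG), outcome("ORR", source=REG)],
            [outcome("OS")],
            [result(outcome("OS"), p=0.01), result(demoted, p=0.40)],
        )
        assert verdict.value is Favorability.FAVORS_SIGNIFICANCE
        assert verdict.trigger is TriggerRule.B

    def test_new_non_significant_safety_primary_favors(self):
        new = outcome("grade 3+ adverse events", outcome_type="safety")
        verdict = _assess(
            [outcome("OS", source=REG)],
            [outcome("OS"), new],
            [result(outcome("OS"), p=0.2), result(new, p=0.60)],
        )
        assert verdict.value is Favorability.FAVORS_SIGNIFICANCE
        assert verdict.trigger is TriggerRule.C

    def test_new_non_significant_efficacy_primary_does_not_favor(self):
        new = outcome("ORR")
        verdict = _assess(
            [outcome("OS", source=REG)],
            [outcome("OS"), new],
            [result(outcome("OS"), p=0.01), result(new, p=0.30)],
        )
        assert verdict.value is Favorability.DOES_NOT_FAVOR
        assert verdict.trigger is TriggerRule.NONE

    def test_missing_summary_measure_is_non_assessable(self):
        new = outcome("ORR")
        verdict = _assess(
            [outcome("OS", source=REG)],
            [outcome("OS"), new],
            [result(outcome("OS"), p=0.01), result(new, reported=False)],
        )
        assert verdict.value is Favorability.NON_ASSESSABLE

    def test_removed_outcome_without_any_article_result_is_non_assessable(self):
        verdict = _assess(
            [outcome("OS", source=REG), outcome("ORR", source=REG)],
            [outcome("OS")],
            [result(outcome("OS"), p=0.01)],  # no ORR result anywhere
        )
        assert verdict.value is Favorability.NON_ASSESSABLE

    def test_changed_definition_with_reported_result_does_not_favor(self):
        verdict = _assess(
            [outcome("OS", time_frame="3 years", source=REG)],
            [outcome("OS", time_frame="5 years")],
            [result(outcome("OS"), p=0.01)],
            category=SwitchCategory.SWITCH_DEFINITION,
        )
        assert verdict.value is Favorability.DOES_NOT_FAVOR

    def test_verdict_invariant_to_results_order(self):
        new = outcome("ORR")
        results = [result(outcome("OS"), p=0.3), result(new, p=0.01)]
        for ordering in (results, results[::-1]):
            verdict = _assess(
                [outcome("OS", source=REG)], [outcome("OS"), new], ordering
            )
            assert verdict.value is Favorability.FAVORS_SIGNIFICANCE

    @pytest.mark.parametrize(
        "category",
        [
            SwitchCategory.NO_SWITCH,
            SwitchCategory.IMPRECISE_REGISTRATION,
            SwitchCategory.NON_ASSESSABLE,
        ],
    )
    def test_defined_only_for_switch_categories(self, category):
        match = match_outcomes([outcome("OS", source=REG)], [outcome("OS")])
        with pytest.raises(ValueError):
            assess_favorability(category, match, [])
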