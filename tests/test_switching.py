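"""Retrospective registration and primary-outcome switch classification."""

import pytest
from hypothesis import given, settings, strategies as st

from trialaudit.model import OutcomeSource, SwitchCategory
from trialaudit.switching import (
    OutcomeOverride,
    classify_switch,
    is_retrospective,
    match_outcomes,
    pick_registry_outcomes,
)
from trialaudit.model import RegistryInfo

from conftest import make_record, outcome

REG = OutcomeSource.REGISTRY_ORIGINAL


class TestIsRetrospective:
    @pytest.mark.parametrize(
        "reg,start,expected",
        [
            ("2010-05-01", "2010-03-01", True),
            ("2010-03", "2010-03", False),  # "after" is strict
            ("2009-12-31", "2010-01-01", False),
            ("2010-03-20", "2010-03", False),  # coarser precision wins
            ("2010-04", "2010-03-05", True),
        ],
    )
    def test_strict_comparison(self, reg, start, expected):
        assert is_retrospective(reg, start) is expected

    def test_missing_date_is_non_assessable(self):
        with pytest.raises(ValueError, match="non-assessable"):
            is_retrospective(None, "2010-01-01")


class TestPickRegistryOutcomes:
    def test_original_preferred_over_current(self):
        os_, pfs = outcome("OS", source=REG), outcome("PFS", source=REG)
        reg = RegistryInfo(
            original_primary_outcomes=[os_], current_primary_outcomes=[pfs]
        )
        assert pick_registry_outcomes(reg) == [os_]

    def test_current_used_only_as_fallback(self):
        pfs = outcome("PFS", source=REG)
        reg = RegistryInfo(current_primary_outcomes=[pfs])
        assert pick_registry_outcomes(reg) == [pfs]

    def test_no_outcome_errors(self):
        with pytest.raises(ValueError):
            pick_registry_outcomes(RegistryInfo())


class TestMatchOutcomes:
    def test_identical_outcomes_pair_with_no_changes(self):
        m = match_outcomes([outcome("OS", source=REG)], [outcome("OS")])
        assert len(m.matched_pairs) == 1
        assert m.matched_pairs[0].changed_fields == frozenset()
        assert not m.unmatched_registered and not m.unmatched_article

    def test_time_frame_change_recorded(self):
        m = match_outcomes(
            [outcome("OS", time_frame="3 years", source=REG)],
            [outcome("OS", time_frame="5 years")],
        )
        assert m.matched_pairs[0].changed_fields == frozenset({"time_frame"})

    def test_metric_change_recorded(self):
        m = match_outcomes(
            [outcome("OS", metric="time to event", source=REG)],
            [outcome("OS", metric="proportion at 1 year")],
        )
        assert m.matched_pairs[0].changed_fields == frozenset({"metric"})

    def test_added_outcome_lands_in_unmatched_article(self):
        m = match_outcomes(
            [outcome("OS", source=REG)], [outcome("OS"), outcome("ORR")]
        )
        assert len(m.matched_pairs) == 1
        assert [o.variable for o in m.unmatched_article] == ["ORR"]

    def test_matching_is_case_and_whitespace_insensitive(self):
        m = match_outcomes(
            [outcome("Overall  Survival", source=REG)], [outcome("overall survival")]
        )
        assert len(m.matched_pairs) == 1

    def test_override_asserts_equivalence_and_definition_change(self):
        ov = OutcomeOverride("OS", "death from any cause", definition_changed=True)
        m = match_outcomes(
            [outcome("OS", source=REG)], [outcome("death from any cause")], [ov]
        )
        assert len(m.matched_pairs) == 1
        assert "definition" in m.matched_pairs[0].changed_fields


class TestClassifySwitch:
    def test_identical_primaries_no_switch(self):
        assert classify_switch(make_record()) is SwitchCategory.NO_SWITCH

    def test_unclear_article_primary_is_non_assessable(self):
        rec = make_record(clearly_identified=False, published=[])
        assert classify_switch(rec) is SwitchCategory.NON_ASSESSABLE

    def test_imprecise_registration_takes_precedence_over_switch_flags(self):
        rec = make_record(
            imprecise=True,
            registered=[outcome("clinical outcomes", source=REG)],
            published=[outcome("OS")],
        )
        assert classify_switch(rec) is SwitchCategory.IMPRECISE_REGISTRATION

    def test_flag_truth_table(self):
        """All four (added/removed, definition-change) combinations."""
        os_reg = outcome("OS", source=REG)
        os_reg_changed = outcome("OS", time_frame="5 years", source=REG)
        cases = [
            ([os_reg], [outcome("OS")], SwitchCategory.NO_SWITCH),
            ([os_reg], [outcome("OS"), outcome("PFS")],
             SwitchCategory.SWITCH_ADD_REMOVE),
            ([os_reg_changed], [outcome("OS")], SwitchCategory.SWITCH_DEFINITION),
            ([os_reg_changed, outcome("ORR", source=REG)], [outcome("OS")],
             SwitchCategory.SWITCH_COMBINATION),
        ]
        for registered, published, expected in cases:
            rec = make_record(registered=registered, published=published)
            assert classify_switch(rec) is expected

    def test_demotion_without_replacement_is_add_remove(self):
        # registered OS demoted, PFS newly primary
        rec = make_record(
            registered=[outcome("OS", source=REG)], published=[outcome("PFS")]
        )
        assert classify_switch(rec) is SwitchCategory.SWITCH_ADD_REMOVE

    @given(st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_to_outcome_listing_order(self, rnd):
        registered = [
            outcome("OS", source=REG),
            outcome("PFS", time_frame="1 year", source=REG),
            outcome("ORR", source=REG),
        ]
        published = [
            outcome("PFS", time_frame="2 years"),
            outcome("OS"),
            outcome("QoL"),
        ]
        rnd.shuffle(registered)
        rnd.shuffle(published)
        rec = make_record(registered=registered, published=published)
        assert classify_switch(rec) is SwitchCategory.SWITCH_COMBINATION
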