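"""Checklist completeness scoring: roll-up rule, skip logic, fallbacks."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from trialaudit.model import (
    Answer,
    ArticleInfo,
    BlindingStatus,
    ItemRating,
    OutcomeSource,
    RegistryInfo,
)
from trialaudit.scoring import (
    rate_blinding,
    rate_item,
    rate_item_6a,
    rate_trial_overall,
    score_trial,
    select_primary_outcome,
)

from conftest import Y, N, NA, make_record, outcome, result

C, P, NR, NAP = (
    ItemRating.COMPLETE,
    ItemRating.PARTIAL,
    ItemRating.NOT_REPORTED,
    ItemRating.NOT_APPLICABLE,
)


def oracle_rate(vec):
    """Independent counting formulation of the three-case rule."""
    k = len(vec)
    n_na = sum(1 for a in vec if a == Answer.NA)
    n_yes = sum(1 for a in vec if a == Answer.YES)
    n_no = sum(1 for a in vec if a == Answer.NO)
    if n_na == k:
        return NAP
    if n_yes == k - n_na:
        return C
    if n_no == k - n_na:
        return NR
    return P


class TestRateItem:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([Y] * 7, C),
            ([Y, Y, Y, Y, Y, NA, Y], C),  # NA excluded from the denominator
            ([Y, N, Y], P),
            ([N, N, N], NR),
            ([NA, NA], NAP),
            ([N, NA], NR),
        ],
    )
    def test_cases(self, vec, expected):
        assert rate_item(vec) is expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            rate_item([])

    @pytest.mark.parametrize("k", range(1, 8))
    def test_matches_enumeration_oracle(self, k):
        for vec in itertools.product(list(Answer), repeat=k):
            assert rate_item(list(vec)) is oracle_rate(vec)

    @given(
        st.lists(st.sampled_from(list(Answer)), min_size=1, max_size=7),
        st.data(),
    )
    @settings(derandomize=True, max_examples=200)
    def test_flipping_no_to_yes_never_decreases_rating(self, vec, data):
        order = {NR: 0, P: 1, C: 2}
        if Answer.NO not in vec:
            return
        i = data.draw(
            st.sampled_from([j for j, a in enumerate(vec) if a == Answer.NO])
        )
        before = rate_item(vec)
        flipped = list(vec)
        flipped[i] = Answer.YES
        after = rate_item(flipped)
        assert order[after] >= order[before]


class TestRateItem6a:
    @pytest.mark.parametrize(
        "vectors,expected",
        [
            ([[Y] * 7, [Y] * 7], C),
            ([[Y] * 7, [Y] * 6 + [N]], P),  # complete only if every outcome is
            ([[N] * 7], NR),
            ([[N] * 7, [N] * 7], NR),
        ],
    )
    def test_multi_outcome_blending(self, vectors, expected):
        assert rate_item_6a(vectors) is expected

    def test_blending_matches_pairwise_enumeration(self):
        # every pair of per-outcome ratings follows the three-case rule
        samples = {C: [Y] * 7, P: [Y] * 6 + [N], NR: [N] * 7}
        for r1, r2 in itertools.product(samples, repeat=2):
            expected = C if (r1, r2) == (C, C) else NR if (r1, r2) == (NR, NR) else P
            assert rate_item_6a([samples[r1], samples[r2]]) is expected

    def test_no_outcome_rejected(self):
        with pytest.raises(ValueError):
            rate_item_6a([])


class TestRateBlinding:
    def test_unblinded_trial_skips_to_not_applicable(self):
        assert rate_blinding(BlindingStatus.UNBLINDED, None, None) is NAP
        assert rate_blinding(BlindingStatus.NOT_REPORTED, None, None) is NAP

    def test_blinded_with_irrelevant_similarity_subitem(self):
        assert rate_blinding(BlindingStatus.BLINDED, [Y, Y], [NA]) is C

    def test_blinded_partial(self):
        assert rate_blinding(BlindingStatus.BLINDED, [Y, N], [Y]) is P

    def test_answers_for_unblinded_trial_rejected(self):
        with pytest.raises(ValueError):
            rate_blinding(BlindingStatus.UNBLINDED, [Y, Y], [Y])


class TestSelectPrimaryOutcome:
    def test_clearly_identified_passes_through(self):
        two = [outcome("os"), outcome("pfs")]
        sel = select_primary_outcome(
            ArticleInfo(primary_clearly_identified=True, primary_outcomes=two),
            RegistryInfo(),
        )
        assert sel.outcomes == two and not sel.imputed

    def test_fallback_order(self):
        obj = outcome("objective outcome")
        ssc = outcome("sample size outcome")
        reg = outcome("registered outcome", source=OutcomeSource.REGISTRY_ORIGINAL)
        listed = outcome("first listed")
        registry = RegistryInfo(original_primary_outcomes=[reg])
        art = ArticleInfo(
            primary_clearly_identified=False,
            objective_outcome=obj,
            sample_size_outcome=ssc,
            all_outcome_results=[result(listed)],
        )
        assert select_primary_outcome(art, registry).outcomes == [obj]
        art.objective_outcome = None
        assert select_primary_outcome(art, registry).outcomes == [ssc]
        art.sample_size_outcome = None
        assert select_primary_outcome(art, registry).outcomes == [reg]
        assert select_primary_outcome(art, registry).imputed
        assert select_primary_outcome(art, RegistryInfo()).outcomes == [listed]

    def test_no_candidate_errors(self):
        with pytest.raises(ValueError, match="no outcome available"):
            select_primary_outcome(
                ArticleInfo(primary_clearly_identified=False), RegistryInfo()
            )


class TestOverallRating:
    def _ratings(self, **overrides):
        base = {k: C for k in ("6a", "8a", "9", "11", "13a", "13b", "17a", "19", "23")}
        base.update(overrides)
        return base

    def test_unblinded_trial_can_still_be_overall_complete(self):
        assert rate_trial_overall(self._ratings(**{"11": NAP})) is C

    def test_single_partial_item_makes_trial_partial(self):
        assert rate_trial_overall(self._ratings(**{"19": P})) is P

    def test_all_not_reported(self):
        assert rate_trial_overall({k: NR for k in self._ratings()}) is NR

    def test_missing_item_rejected(self):
        ratings = self._ratings()
        del ratings["23"]
        with pytest.raises(ValueError, match="23"):
            rate_trial_overall(ratings)


class TestScoreTrial:
    def test_complete_unblinded_record(self):
        ratings = score_trial(make_record())
        assert ratings["11"] is NAP
        assert all(
            ratings[k] is C for k in ("6a", "8a", "9", "13a", "13b", "17a", "19", "23")
        )
        assert rate_trial_overall(ratings) is C

    def test_missing_item_answers_reported_with_trial_id(self):
        rec = make_record()
        del rec.item_answers["19"]
        with pytest.raises(ValueError, match="item 19"):
            score_trial(rec)
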