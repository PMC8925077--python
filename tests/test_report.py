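"""Percent convention, cohort aggregation and report rendering."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from trialaudit.report import (
    CohortSummary,
    check_block_sums,
    percent,
    render_report,
    summarize_cohort,
)

from conftest import make_record


class TestPercent:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [
            (6, 16, 38),   # 37.5 -> ties round up
            (49, 101, 49),
            (0, 10, 0),
            (55, 101, 54),
            (51, 101, 50),
            (1, 200, 1),   # 0.5 -> up
            (10, 10, 100),
        ],
    )
    def test_half_up_rounding(self, count, denom, expected):
        assert percent(count, denom) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    def test_count_above_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(5, 4)

    @given(st.integers(1, 500), st.data())
    @settings(derandomize=True, max_examples=200)
    def test_matches_decimal_half_up(self, denom, data):
        from decimal import Decimal, ROUND_HALF_UP

        count = data.draw(st.integers(0, denom))
        oracle = int(
            (Decimal(100 * count) / Decimal(denom)).quantize(
                Decimal("1"), rounding=ROUND_HALF_UP
            )
        )
        assert percent(count, denom) == oracle


class TestSummarizeCohort:
    def test_single_complete_trial(self):
        summary = summarize_cohort([make_record()])
        e = summary.entry("completeness", "overall_complete")
        assert (e.count, e.denominator, e.percent) == (1, 1, 100)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_permutation_invariant(self, paper_cohort):
        assert summarize_cohort(paper_cohort) == summarize_cohort(
            list(reversed(paper_cohort))
        )

    def test_categorical_blocks_sum_to_their_denominators(self, paper_cohort):
        summary = summarize_cohort(paper_cohort)
        assert check_block_sums(summary) == []

    def test_counts_are_additive_over_concatenation(self, paper_cohort):
        half = len(paper_cohort) // 2
        a = summarize_cohort(paper_cohort[:half])
        b = summarize_cohort(paper_cohort[half:])
        whole = summarize_cohort(paper_cohort)
        for block, entries in whole.blocks.items():
            for name, e in entries.items():
                ea, eb = a.blocks[block][name], b.blocks[block][name]
                assert ea.count + eb.count == e.count
                assert ea.denominator + eb.denominator == e.denominator

    def test_nested_denominators(self, paper_cohort):
        summary = summarize_cohort(paper_cohort)
        n = summary.n
        blinded = summary.entry("completeness", "blinded_trials").count
        assert summary.entry("completeness", "blinding_complete").denominator == blinded
        switched = summary.entry("selective_reporting", "switched").count
        assert (
            summary.entry("selective_reporting", "switch_add_remove").denominator
            == switched
        )
        assessable = summary.entry(
            "selective_reporting", "favorability_assessable"
        ).count
        assert (
            summary.entry("selective_reporting", "favors_significance").denominator
            == assessable
        )
        assert summary.entry("completeness", "overall_complete").denominator == n


class TestRenderReport:
    def test_json_round_trip(self, paper_cohort):
        summary = summarize_cohort(paper_cohort)
        parsed = CohortSummary.from_dict(json.loads(render_report(summary, "json")))
        assert parsed == summary

    def test_csv_percent_column_recomputes(self, paper_cohort):
        summary = summarize_cohort(paper_cohort)
        lines = render_report(summary, "csv").strip().splitlines()[1:]
        assert len(lines) > 30
        for line in lines:
            _, _, count, denom, pct = line.split(",")
            if pct:
                assert int(pct) == percent(int(count), int(denom))
            else:
                assert denom == "0"

    def test_markdown_has_one_row_per_indicator(self, paper_cohort):
        summary = summarize_cohort(paper_cohort)
        md = render_report(summary, "markdown")
        n_rows = sum(
            1
            for line in md.splitlines()
            if line.startswith("|") and "---" not in line and "Indicator" not in line
        )
        assert n_rows == sum(len(v) for v in summary.blocks.values())

    def test_unknown_format_rejected(self, paper_cohort):
        with pytest.raises(ValueError):
            render_report(summarize_cohort(paper_cohort), "xml")
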