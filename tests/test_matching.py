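import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import greedy_rescan
from sheetmerge.io_csv import Column, Spreadsheet
from sheetmerge.matching import (
    MergeConfig,
    MergeGroup,
    MergePlan,
    PairAssignment,
    PairRecord,
    apply_merge,
    choose_label,
    form_groups,
    greedy_select,
    merge_sheets,
)
from sheetmerge.similarity import SimilarityMatrix


def matrix(rows, pair=("j", "k")):
    return SimilarityMatrix(sheet_pair=pair, scores=np.array(rows, dtype=float))


def sheet(sheet_id, *headers, n_rows=1, fill="v"):
    cols = tuple(
        Column(i, h, tuple(fill for _ in range(n_rows)), "discrete")
        for i, h in enumerate(headers)
    )
    return Spreadsheet(sheet_id, cols)


class TestGreedySelect:
    def test_delete_row_and_column_procedure(self):
        pa = greedy_select(matrix([[0.9, 0.6], [0.8, 0.7]]), MergeConfig(0.5))
        assert [(p.row, p.col, p.score, p.above_threshold) for p in pa.pairs] == [
            (0, 0, 0.9, True),
            (1, 1, 0.7, True),
        ]

    def test_single_cell_below_threshold_flagged(self):
        pa = greedy_select(matrix([[0.4]]), MergeConfig(0.5))
        assert pa.pairs == (PairRecord(0, 0, 0.4, False),)

    def test_row_exhausted_leaves_column_unpaired(self):
        pa = greedy_select(matrix([[0.9, 0.85]]), MergeConfig(0.5))
        assert [(p.row, p.col) for p in pa.pairs] == [(0, 0)]

    def test_score_at_threshold_is_accepted(self):
        pa = greedy_select(matrix([[0.5]]), MergeConfig(0.5))
        assert pa.pairs[0].above_threshold

    def test_ties_break_to_smallest_row_then_column(self):
        pa = greedy_select(matrix([[0.5, 0.5], [0.5, 0.5]]), MergeConfig(0.0))
        assert [(p.row, p.col) for p in pa.pairs] == [(0, 0), (1, 1)]

    @given(
        n_rows=st.integers(1, 8),
        n_cols=st.integers(1, 8),
        seed=st.integers(0, 2**16),
    )
    def test_matches_rescan_reference(self, n_rows, n_cols, seed):
        rng = random.Random(seed)
        rows = [[rng.random() for _ in range(n_cols)] for _ in range(n_rows)]
        pa = greedy_select(matrix(rows), MergeConfig(0.5))
        assert [
            (p.row, p.col, p.score, p.above_threshold) for p in pa.pairs
        ] == greedy_rescan(rows, 0.5)

    def test_raising_threshold_never_gains_accepted_pairs(self):
        rng = random.Random(3)
        rows = [[rng.random() for _ in range(6)] for _ in range(6)]
        counts = [
            sum(p.above_threshold for p in greedy_select(matrix(rows), MergeConfig(t)).pairs)
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestChooseLabel:
    @pytest.mark.parametrize(
        "headers,expected",
        [
            ({("A", "gender"), ("B", "sex")}, "sex"),
            ({("B", "grade")}, "grade"),
            ({("A", "abc"), ("B", "xyz")}, "abc"),  # length tie -> lexicographic
        ],
    )
    def test_shortest_then_lexicographic(self, headers, expected):
        assert choose_label(headers) == expected


class TestFormGroups:
    def test_single_accepted_pair(self):
        sheets = [sheet("A", "gender"), sheet("B", "sex", "grade")]
        pa = PairAssignment(("A", "B"), (PairRecord(0, 0, 0.9, True), ))
        plan = form_groups([pa], sheets)
        assert {g.members for g in plan.groups} == {
            frozenset({("A", "gender"), ("B", "sex")}),
            frozenset({("B", "grade")}),
        }

    def test_transitive_via_third_sheet(self):
        sheets = [sheet("A", "x"), sheet("B", "y"), sheet("C", "z")]
        assignments = [
            PairAssignment(("A", "B"), (PairRecord(0, 0, 0.3, False),)),
            PairAssignment(("A", "C"), (PairRecord(0, 0, 0.8, True),)),
            PairAssignment(("B", "C"), (PairRecord(0, 0, 0.8, True),)),
        ]
        plan = form_groups(assignments, sheets)
        assert {g.members for g in plan.groups} == {
            frozenset({("A", "x"), ("B", "y"), ("C", "z")})
        }

    def test_no_accepted_pairs_gives_all_singletons(self):
        sheets = [sheet("A", "x"), sheet("B", "y")]
        pa = PairAssignment(("A", "B"), (PairRecord(0, 0, 0.1, False),))
        plan = form_groups([pa], sheets)
        assert all(len(g.members) == 1 for g in plan.groups)
        assert len(plan.groups) == 2

    def test_invariant_to_assignment_order(self):
        sheets = [sheet("A", "x"), sheet("B", "y"), sheet("C", "z")]
        assignments = [
            PairAssignment(("A", "B"), (PairRecord(0, 0, 0.9, True),)),
            PairAssignment(("A", "C"), (PairRecord(0, 0, 0.2, False),)),
            PairAssignment(("B", "C"), (PairRecord(0, 0, 0.9, True),)),
        ]
        forward = form_groups(assignments, sheets)
        backward = form_groups(list(reversed(assignments)), sheets)
        assert forward == backward

    def test_duplicate_sheet_pair_rejected(self):
        sheets = [sheet("A", "x"), sheet("B", "y")]
        pa = PairAssignment(("A", "B"), (PairRecord(0, 0, 0.9, True),))
        pb = PairAssignment(("B", "A"), (PairRecord(0, 0, 0.9, True),))
        with pytest.raises(ValueError, match="more than once"):
            form_groups([pa, pb], sheets)


class TestApplyMerge:
    def test_worked_example_rows(self, worked_example):
        sheets, _, truth = worked_example
        table = apply_merge(sheets, truth)
        assert table.group_labels == ["sex", "grade"]
        assert table.rows[0] == {"sex": "male"}  # grade cell empty for A's rows
        assert table.rows[2] == {"sex": "male", "grade": "moderate"}
        assert table.provenance == ["A", "A", "B", "B", "B"]

    def test_two_sheets_no_merges_is_disjoint_union(self):
        sheets = [sheet("A", "x", "y"), sheet("B", "z")]
        plan = MergePlan(
            [
                MergeGroup("x", frozenset({("A", "x")})),
                MergeGroup("y", frozenset({("A", "y")})),
                MergeGroup("z", frozenset({("B", "z")})),
            ]
        )
        table = apply_merge(sheets, plan)
        assert len(table.group_labels) == 3
        assert table.rows[0].keys() == {"x", "y"}
        assert table.rows[1].keys() == {"z"}

    def test_plan_not_a_partition_is_an_error(self):
        sheets = [sheet("A", "x")]
        plan = MergePlan([MergeGroup("q", frozenset({("A", "q")}))])
        with pytest.raises(ValueError, match="partition"):
            apply_merge(sheets, plan)

    def test_overlapping_groups_rejected_at_construction(self):
        with pytest.raises(ValueError, match="more than one group"):
            MergePlan(
                [
                    MergeGroup("a", frozenset({("A", "x")})),
                    MergeGroup("b", frozenset({("A", "x")})),
                ]
            )


class TestConfigAndPipeline:
    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_threshold_validation(self, bad):
        with pytest.raises(ValueError):
            MergeConfig(threshold=bad)

    def test_worked_example_end_to_end_label(self, worked_example):
        sheets, lex, _ = worked_example
        plan, assignments = merge_sheets(sheets, lex)
        labels = {g.label for g in plan.groups}
        assert labels == {"sex", "grade"}
        # diagnostics carry the rejected gender~grade comparison too
        assert len(assignments) == 1
        assert len(assignments[0].pairs) == 1  # 1x2 matrix pairs once

    def test_duplicate_sheet_ids_rejected(self):
        from sheetmerge.lexicon import CollocateLexicon

        with pytest.raises(ValueError, match="duplicate sheet ids"):
            merge_sheets([sheet("A", "x"), sheet("A", "y")], CollocateLexicon({}))
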