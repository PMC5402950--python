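"""Scoring a merge plan against a hand-curated ground truth.

Accuracy is per physical column: a column is correct when its predicted
group's member set equals its true group's member set (singletons in both
count as correct).  Every incorrect column falls into exactly one of three
error categories:

* ungrouped   — left alone by the algorithm but grouped in the truth,
* overgrouped — grouped by the algorithm but a singleton in the truth,
* misgrouped  — in a (non-singleton) group in both, but not the right one.

The counts therefore always sum to the number of columns.  Group labels are
ignored — grouping, not naming, is what is scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_csv import Spreadsheet
from .lexicon import CollocateLexicon
from .matching import ColumnRef, MergeConfig, MergeGroup, MergePlan, merge_sheets
from .termsets import AbbreviationDict

#: Ground truth has exactly the shape of a merge plan (a labeled partition).
GroundTruth = MergePlan


@dataclass(frozen=True)
class EvaluationReport:
    n_columns: int
    n_correct: int
    errors_ungrouped: int  # split by the algorithm, together in truth
    errors_overgrouped: int  # grouped by the algorithm, singleton in truth
    errors_misgrouped: int  # grouped in both, but member sets differ

    def __post_init__(self) -> None:
        total = (
            self.n_correct
            + self.errors_ungrouped
            + self.errors_overgrouped
            + self.errors_misgrouped
        )
        if total != self.n_columns:
            raise ValueError("error categories must partition the columns")

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_columns if self.n_columns else 1.0

    def as_dict(self) -> dict:
        return {
            "n_columns": self.n_columns,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "errors_ungrouped": self.errors_ungrouped,
            "errors_overgrouped": self.errors_overgrouped,
            "errors_misgrouped": self.errors_misgrouped,
        }


def _group_of(plan: MergePlan) -> dict[ColumnRef, frozenset[ColumnRef]]:
    return {m: g.members for g in plan.groups for m in g.members}


def score(plan: MergePlan, truth: GroundTruth) -> EvaluationReport:
    """Per-column accuracy plus the three-way error taxonomy.

    The plan and truth must partition the same column set; a mismatch is an
    error listing the difference.
    """
    plan_of = _group_of(plan)
    truth_of = _group_of(truth)
    if set(plan_of) != set(truth_of):
        only_plan = sorted(set(plan_of) - set(truth_of))
        only_truth = sorted(set(truth_of) - set(plan_of))
        raise ValueError(
            f"plan and truth cover different columns; "
            f"only in plan: {only_plan}; only in truth: {only_truth}"
        )

    n_correct = cat1 = cat2 = cat3 = 0
    for column, predicted in plan_of.items():
        actual = truth_of[column]
        if predicted == actual:
            n_correct += 1
        elif len(predicted) == 1:  # actual is larger, else sets would be equal
            cat1 += 1
        elif len(actual) == 1:
            cat2 += 1
        else:
            cat3 += 1
    return EvaluationReport(
        n_columns=len(plan_of),
        n_correct=n_correct,
        errors_ungrouped=cat1,
        errors_overgrouped=cat2,
        errors_misgrouped=cat3,
    )


def _drop_columns(plan: MergePlan, drop: set[ColumnRef]) -> MergePlan:
    groups = []
    for g in plan.groups:
        members = g.members - drop
        if members:
            groups.append(MergeGroup(label=g.label, members=members))
    return MergePlan(groups)


def exclude_exact_matches(
    plan: MergePlan, truth: GroundTruth, sheets: Sequence[Spreadsheet]
) -> tuple[MergePlan, GroundTruth]:
    """Remove every column whose lowercased header occurs in more than one
    sheet, from both partitions.

    Exact header matches are the easy part of the problem; re-scoring the
    remainder isolates how well the similarity machinery does on columns that
    only semantics can match.
    """
    sheets_with: dict[str, set[str]] = {}
    for sheet in sheets:
        for col in sheet.columns:
            sheets_with.setdefault(col.header.lower(), set()).add(sheet.sheet_id)
    shared = {h for h, owners in sheets_with.items() if len(owners) > 1}
    drop = {
        (sheet.sheet_id, col.header)
        for sheet in sheets
        for col in sheet.columns
        if col.header.lower() in shared
    }
    return _drop_columns(plan, drop), _drop_columns(truth, drop)


def threshold_sweep(
    sheets: Sequence[Spreadsheet],
    lex: CollocateLexicon,
    truth: GroundTruth,
    thresholds: Sequence[float],
    abbrev: AbbreviationDict | None = None,
) -> list[tuple[float, float]]:
    """Re-run the full pipeline at each threshold and report accuracy.

    Deterministic for fixed inputs; thresholds must be sorted ascending.
    A very low threshold accepts every greedy pair (over-merging), a very
    high one yields an all-singleton plan, and accuracy typically peaks in
    between — the curve this sweep exists to draw.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    curve = []
    for t in thresholds:
        plan, _ = merge_sheets(sheets, lex, MergeConfig(threshold=t), abbrev=abbrev)
        curve.append((float(t), score(plan, truth).accuracy))
    return curve
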