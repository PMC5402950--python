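"""Greedy pair selection, transitive grouping, labeling, and merge application.

For every pair of spreadsheets the matcher repeatedly takes the globally
maximal cell of the similarity matrix, records the corresponding column pair,
and deletes its row and column until one side is exhausted.  Pairs scoring at
or above the threshold (default 0.5) become edges; connected components over
those edges across *all* sheet pairs define the merge groups, which makes
merging transitive: two columns whose direct similarity falls below the
threshold still land in one group when a third sheet's column links them.
Below-threshold pairs are recorded for diagnostics but never create edges.
Within-sheet merging never happens — matrices are only built between distinct
sheets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_csv import MergedTable, Spreadsheet
from .lexicon import CollocateLexicon, expand
from .similarity import SimilarityMatrix, build_cs_matrix
from .termsets import AbbreviationDict, expand_abbreviations, tokenize_column

logger = logging.getLogger(__name__)

ColumnRef = tuple[str, str]  # (sheet_id, header)


@dataclass(frozen=True)
class MergeConfig:
    """Pipeline knobs; the similarity threshold is the only one that matters."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


@dataclass(frozen=True)
class PairRecord:
    row: int  # column index in sheet j
    col: int  # column index in sheet k
    score: float
    above_threshold: bool


@dataclass(frozen=True)
class PairAssignment:
    """Greedy matching result for one ordered sheet pair."""

    sheet_pair: tuple[str, str]
    pairs: tuple[PairRecord, ...]


def greedy_select(matrix: SimilarityMatrix, config: MergeConfig = MergeConfig()) -> PairAssignment:
    """Select column pairs by repeated global argmax with row/column deletion.

    Ties break deterministically to the smallest row index, then the smallest
    column index (row-major argmax).  Every selected pair is flagged above or
    below the threshold; selection itself ignores the threshold so that
    diagnostics show near-misses too.
    """
    scores = np.array(matrix.scores, dtype=float, copy=True)
    n_rows, n_cols = scores.shape
    pairs: list[PairRecord] = []
    for _ in range(min(n_rows, n_cols)):
        flat = int(np.argmax(scores))
        r, c = divmod(flat, n_cols)
        score = float(matrix.scores[r, c])
        pairs.append(
            PairRecord(row=r, col=c, score=score, above_threshold=score >= config.threshold)
        )
        scores[r, :] = -np.inf
        scores[:, c] = -np.inf
    return PairAssignment(sheet_pair=matrix.sheet_pair, pairs=tuple(pairs))


@dataclass(frozen=True)
class MergeGroup:
    label: str
    members: frozenset[ColumnRef]
    # Not part of equality: a loaded plan recomputes it from the label.
    label_overridden: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("merge group must have at least one member")


@dataclass(frozen=True)
class MergePlan:
    """A partition of every input column into labeled groups."""

    groups: tuple[MergeGroup, ...]

    def __init__(self, groups: Iterable[MergeGroup]):
        object.__setattr__(self, "groups", tuple(groups))
        seen: set[ColumnRef] = set()
        for g in self.groups:
            overlap = seen & g.members
            if overlap:
                raise ValueError(f"columns in more than one group: {sorted(overlap)}")
            seen |= g.members

    def columns(self) -> frozenset[ColumnRef]:
        return frozenset(m for g in self.groups for m in g.members)


def choose_label(members: Iterable[ColumnRef]) -> str:
    """Default group label: the shortest member header; ties break to the
    lexicographically smallest."""
    headers = [h for _, h in members]
    if not headers:
        raise ValueError("cannot label an empty group")
    return min(headers, key=lambda h: (len(h), h))


def _column_order(sheets: Sequence[Spreadsheet]) -> dict[ColumnRef, int]:
    order: dict[ColumnRef, int] = {}
    for sheet in sheets:
        for col in sheet.columns:
            order[(sheet.sheet_id, col.header)] = len(order)
    return order


def form_groups(
    assignments: Iterable[PairAssignment], sheets: Sequence[Spreadsheet]
) -> MergePlan:
    """Connected components over all above-threshold pairs.

    Components implement the transitivity rule directly: a below-threshold
    pair is honored exactly when its two columns are already connected through
    other sheets' accepted pairs, and unpaired columns fall out as singletons.
    The result does not depend on the order in which sheet pairs were
    processed.
    """
    by_id = {s.sheet_id: s for s in sheets}
    graph: nx.Graph = nx.Graph()
    for sheet in sheets:
        for col in sheet.columns:
            graph.add_node((sheet.sheet_id, col.header))
    seen_pairs: set[frozenset[str]] = set()
    for pa in assignments:
        sid_j, sid_k = pa.sheet_pair
        key = frozenset((sid_j, sid_k))
        if key in seen_pairs:
            raise ValueError(f"sheet pair {pa.sheet_pair} assigned more than once")
        seen_pairs.add(key)
        sheet_j, sheet_k = by_id[sid_j], by_id[sid_k]
        for rec in pa.pairs:
            u = (sid_j, sheet_j.columns[rec.row].header)
            v = (sid_k, sheet_k.columns[rec.col].header)
            if rec.above_threshold:
                logger.info("accept %s ~ %s (score %.3f)", u, v, rec.score)
                graph.add_edge(u, v)
            else:
                logger.info("reject %s ~ %s (score %.3f)", u, v, rec.score)

    order = _column_order(sheets)
    components = sorted(
        (frozenset(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: min(order[m] for m in comp),
    )
    return MergePlan(
        MergeGroup(label=choose_label(comp), members=comp) for comp in components
    )


def apply_merge(sheets: Sequence[Spreadsheet], plan: MergePlan) -> MergedTable:
    """Stack every input row under the plan's group labels.

    Values are copied verbatim; groups absent from a row's source sheet yield
    empty cells.  The plan must partition exactly the sheets' columns.
    """
    actual = frozenset(
        (s.sheet_id, c.header) for s in sheets for c in s.columns
    )
    planned = plan.columns()
    if planned != actual:
        missing = sorted(actual - planned)
        unknown = sorted(planned - actual)
        raise ValueError(
            f"plan does not partition the input columns; "
            f"missing from plan: {missing}; unknown to inputs: {unknown}"
        )

    label_of: dict[ColumnRef, str] = {}
    for group in plan.groups:
        for member in group.members:
            label_of[member] = group.label

    order = _column_order(sheets)
    labels = [
        g.label
        for g in sorted(plan.groups, key=lambda g: min(order[m] for m in g.members))
    ]
    rows: list[dict[str, str]] = []
    provenance: list[str] = []
    for sheet in sheets:
        for i in range(sheet.n_rows):
            row = {
                label_of[(sheet.sheet_id, col.header)]: col.values[i]
                for col in sheet.columns
            }
            rows.append(row)
            provenance.append(sheet.sheet_id)
    return MergedTable(group_labels=labels, rows=rows, provenance=provenance)


def merge_sheets(
    sheets: Sequence[Spreadsheet],
    lex: CollocateLexicon,
    config: MergeConfig = MergeConfig(),
    abbrev: AbbreviationDict | None = None,
) -> tuple[MergePlan, list[PairAssignment]]:
    """Full pipeline: term sets -> (optional abbreviation expansion) ->
    collocate expansion -> pairwise similarity -> greedy selection ->
    transitive grouping.  Returns the plan plus per-pair diagnostics."""
    ids = [s.sheet_id for s in sheets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sheet ids: {ids}")
    expanded: dict[str, list] = {}
    for sheet in sheets:
        sets = []
        for col in sheet.columns:
            ts = tokenize_column(col, sheet.sheet_id)
            if abbrev is not None:
                ts = expand_abbreviations(ts, abbrev)
            sets.append(expand(ts, lex))
        expanded[sheet.sheet_id] = sets
    assignments = [
        greedy_select(build_cs_matrix(expanded[a.sheet_id], expanded[b.sheet_id]), config)
        for a, b in combinations(sheets, 2)
    ]
    return form_groups(assignments, sheets), assignments
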