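"""CSV ingestion/export and merge-plan serialization.

Input spreadsheets are RFC 4180 CSV (UTF-8, comma delimiter, first row is the
header row).  Cell values are preserved byte-for-byte throughout the pipeline:
this module is the only place bytes enter or leave, and it never normalises
them.  Merge plans round-trip through a small JSON document so a user can edit
the grouping by hand and re-apply it — the programmatic equivalent of moving
labels between groups in an interactive curation UI.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .termsets import classify_datatype

logger = logging.getLogger(__name__)

#: Name of the provenance column appended to merged output.
SOURCE_COLUMN = "__source"


@dataclass(frozen=True)
class Column:
    """One spreadsheet column: 0-based position, raw header, raw cell values."""

    index: int
    header: str
    values: tuple[str, ...]
    datatype: str

    def __post_init__(self) -> None:
        if not self.header.strip():
            raise ValueError("column header empty after trimming")


@dataclass(frozen=True)
class Spreadsheet:
    """A named table with ordered, equal-length columns."""

    sheet_id: str
    columns: tuple[Column, ...]

    def __post_init__(self) -> None:
        if not self.sheet_id:
            raise ValueError("sheet_id must be non-empty")
        if not self.columns:
            raise ValueError(f"spreadsheet {self.sheet_id!r} has no columns")
        lengths = {len(c.values) for c in self.columns}
        if len(lengths) > 1:
            raise ValueError(f"unequal column lengths in {self.sheet_id!r}: {lengths}")

    @property
    def n_rows(self) -> int:
        return len(self.columns[0].values)

    @property
    def headers(self) -> tuple[str, ...]:
        return tuple(c.header for c in self.columns)


@dataclass
class MergedTable:
    """Merged output: one column per group plus per-row provenance."""

    group_labels: list[str]
    rows: list[dict[str, str]]  # keyed by group label; missing keys mean empty
    provenance: list[str]  # source sheet_id, parallel to rows

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.provenance):
            raise ValueError("rows and provenance differ in length")


def read_csv(path: str | Path, sheet_id: str | None = None) -> Spreadsheet:
    """Read one spreadsheet.

    ``sheet_id`` defaults to the file stem.  Blank header cells become
    ``column_<index>``; ragged (short) rows are padded with empty strings.
    Both repairs are logged.  Duplicate headers are an error because columns
    are addressed by ``(sheet_id, header)`` downstream.
    """
    path = Path(path)
    if sheet_id is None:
        sheet_id = path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty CSV (no header row)")

    headers: list[str] = []
    for i, raw in enumerate(rows[0]):
        if raw.strip():
            headers.append(raw)
        else:
            logger.warning("%s: blank header at index %d renamed to column_%d", path, i, i)
            headers.append(f"column_{i}")
    seen: set[str] = set()
    for h in headers:
        if h in seen:
            raise ValueError(f"{path}: duplicate header {h!r}")
        seen.add(h)

    n_cols = len(headers)
    body: list[list[str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) > n_cols:
            raise ValueError(
                f"{path}:{lineno}: row has {len(row)} cells but only {n_cols} headers"
            )
        if len(row) < n_cols:
            logger.warning(
                "%s:%d: ragged row padded from %d to %d cells", path, lineno, len(row), n_cols
            )
            row = row + [""] * (n_cols - len(row))
        body.append(row)

    columns = tuple(
        Column(
            index=i,
            header=headers[i],
            values=tuple(r[i] for r in body),
            datatype=classify_datatype([r[i] for r in body]),
        )
        for i in range(n_cols)
    )
    return Spreadsheet(sheet_id=sheet_id, columns=columns)


def write_csv(sheet: Spreadsheet, path: str | Path) -> None:
    """Write a spreadsheet back to CSV (used by the fixture generator)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(sheet.headers)
        for i in range(sheet.n_rows):
            writer.writerow([c.values[i] for c in sheet.columns])


def write_merged(table: MergedTable, path: str | Path) -> None:
    """Write the merged table with group labels as headers plus a provenance
    column; values appear exactly as they did in the inputs."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(table.group_labels) + [SOURCE_COLUMN])
        for row, source in zip(table.rows, table.provenance):
            writer.writerow([row.get(label, "") for label in table.group_labels] + [source])


# --- merge-plan JSON -------------------------------------------------------
#
# {"groups": [{"label": "sex", "members": [["A", "gender"], ["B", "sex"]]}]}
#
# The plan is authoritative: apply_merge honours whatever partition it holds,
# which is how hand edits survive a re-merge.


def save_plan(plan, path: str | Path) -> None:
    """Serialize a MergePlan; ``load_plan(save_plan(p)) == p``."""
    doc = {
        "groups": [
            {"label": g.label, "members": [list(m) for m in sorted(g.members)]}
            for g in plan.groups
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_plan(path: str | Path):
    """Load a MergePlan, rejecting documents that are not a partition
    (a column listed in two groups is an error naming the column)."""
    from .matching import MergeGroup, MergePlan  # deferred: avoids import cycle

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"{path}: not a merge plan (missing 'groups')")
    groups = []
    seen: dict[tuple[str, str], str] = {}
    for entry in doc["groups"]:
        label = entry["label"]
        members = frozenset((str(s), str(h)) for s, h in entry["members"])
        if len(members) != len(entry["members"]):
            raise ValueError(f"{path}: duplicate member within group {label!r}")
        for m in members:
            if m in seen:
                raise ValueError(
                    f"{path}: column {m} listed in groups {seen[m]!r} and {label!r}"
                )
            seen[m] = label
        groups.append(MergeGroup(label=label, members=members))
    return MergePlan(groups=groups)
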