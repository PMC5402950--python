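"""Per-column term sets.

Every column contributes a bag-free *term set*: the lowercase unigrams of its
header plus (for discrete columns) the unigrams of all its values.  Term sets
are the raw material for collocate expansion — the merging signal is purely
presence/absence, so duplicates and row order are irrelevant by construction.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids circular import
    from .io_csv import Column

DISCRETE = "discrete"
CONTINUOUS = "continuous"

# Split on any run of non-alphanumerics: "pr.status" -> pr, status;
# "progesterone receptor status" -> three tokens.
_SPLIT = re.compile(r"[^a-z0-9]+")
_PURE_NUMBER = re.compile(r"[0-9]+\Z")


def tokenize(text: str) -> set[str]:
    """Lowercase unigrams of ``text``.

    Pure-number tokens are dropped (a bare "3" carries no lexical signal)
    while mixed alphanumerics such as "a1" or "her2" are kept — exactly the
    behaviour that lets alphanumeric category codes in two unrelated columns
    look alike, a failure mode the evaluation module must be able to exhibit.
    """
    tokens = _SPLIT.split(text.lower())
    return {t for t in tokens if t and not _PURE_NUMBER.fullmatch(t)}


@dataclass(frozen=True)
class TermSet:
    """Unigram set for one column; ``owner`` is ``(sheet_id, column_index)``."""

    owner: tuple[str, int]
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if any(not t for t in self.terms):
            raise ValueError("term sets may not contain empty strings")


def _parses_as_number(value: str) -> bool:
    try:
        x = float(value)
    except ValueError:
        return False
    return math.isfinite(x)


def classify_datatype(values: Iterable[str]) -> str:
    """Classify a column's values as ``discrete`` or ``continuous``.

    Continuous requires both a numeric look (>= 90% of non-empty cells parse
    as finite numbers) and high cardinality (more unique values than
    ``max(10, n/2)``): low-cardinality numeric codes like 0/1 flags remain
    discrete so their values still enter the term set pipeline's scope rules.
    An empty column is discrete.
    """
    non_empty = [v for v in values if v.strip()]
    if not non_empty:
        return DISCRETE
    numeric = sum(1 for v in non_empty if _parses_as_number(v))
    if numeric < 0.9 * len(non_empty):
        return DISCRETE
    if len(set(non_empty)) > max(10, len(non_empty) / 2):
        return CONTINUOUS
    return DISCRETE


def tokenize_column(column: "Column", sheet_id: str = "") -> TermSet:
    """Build the term set for ``column``.

    Discrete columns contribute header and value unigrams; continuous columns
    contribute header unigrams only (raw measurements carry units, not
    vocabulary, and merging continuous data on values is out of scope).
    """
    terms = tokenize(column.header)
    if column.datatype == DISCRETE:
        for value in column.values:
            terms |= tokenize(value)
    return TermSet(owner=(sheet_id, column.index), terms=frozenset(terms))


@dataclass(frozen=True)
class AbbreviationDict:
    """Abbreviation -> expansion phrase, e.g. ``pr -> "prothrombin ratio"``."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for key, expansion in self.entries.items():
            if key != key.lower():
                raise ValueError(f"abbreviation key not lowercase: {key!r}")
            if not expansion.strip():
                raise ValueError(f"empty expansion for abbreviation {key!r}")


def load_abbreviations(path: str | Path) -> AbbreviationDict:
    """Read a two-column CSV ``abbreviation,expansion``."""
    entries: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            key, expansion = row[0].strip().lower(), row[1].strip()
            if key in entries:
                raise ValueError(f"{path}:{lineno}: duplicate abbreviation {key!r}")
            entries[key] = expansion
    return AbbreviationDict(entries=entries)


def expand_abbreviations(ts: TermSet, abbrev: AbbreviationDict) -> TermSet:
    """Add the unigrams of each matched expansion; originals are retained.

    Applied once, not recursively: expansions whose words happen to be
    abbreviations themselves are not chased.
    """
    extra: set[str] = set()
    for term in ts.terms:
        expansion = abbrev.entries.get(term)
        if expansion is not None:
            extra |= tokenize(expansion)
    if not extra:
        return ts
    return TermSet(owner=ts.owner, terms=ts.terms | frozenset(extra))
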