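"""File-backed collocate lexicon and term-set expansion.

A collocate is a word that co-occurs with a target word more often than
chance in a reference corpus.  Expanding a column's term set with the
collocates of each term places the column in a semantic context, so that
"gender" and "sex" — which share values but not headers — end up with heavily
overlapping expanded sets.  The lexicon is a plain TSV file
(``term<TAB>comma-separated collocates``) so it can be authored by hand,
exported from any corpus the user has access to, or generated synthetically.

Expansion is one level deep: collocates of collocates are never queried, and
membership is binary — no frequencies are stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .termsets import TermSet

logger = logging.getLogger(__name__)

#: Packaged lexicon for the worked example's gender column (three terms).
GENDER_COLLOCATES = Path(__file__).parent / "data" / "gender_collocates.tsv"


@dataclass(frozen=True)
class CollocateLexicon:
    """term -> ordered collocate list; everything lowercase, no duplicates."""

    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for term, collocates in self.entries.items():
            if not term or term != term.lower():
                raise ValueError(f"lexicon term must be lowercase, non-empty: {term!r}")
            if len(set(collocates)) != len(collocates):
                raise ValueError(f"duplicate collocates for term {term!r}")
            if any(not c or c != c.lower() for c in collocates):
                raise ValueError(f"collocates of {term!r} must be lowercase, non-empty")

    def lookup(self, term: str) -> list[str]:
        """Collocates of ``term``; empty list when the term is unknown."""
        return list(self.entries.get(term, ()))


def lookup(term: str, lex: CollocateLexicon) -> list[str]:
    return lex.lookup(term)


def load_lexicon(path: str | Path) -> CollocateLexicon:
    """Parse a lexicon TSV.

    Terms are lowercased; duplicate collocates within one term are dropped
    with a warning (order preserved); a line without a tab separator, an
    empty term, or a repeated term is an error reported with its line number.
    """
    entries: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'term<TAB>collocates'")
            term, _, rest = line.partition("\t")
            term = term.strip().lower()
            if not term:
                raise ValueError(f"{path}:{lineno}: empty term")
            if term in entries:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            collocates: list[str] = []
            for raw in rest.split(","):
                c = raw.strip().lower()
                if not c:
                    continue
                if c in collocates:
                    logger.warning("%s:%d: duplicate collocate %r for %r", path, lineno, c, term)
                    continue
                collocates.append(c)
            entries[term] = tuple(collocates)
    return CollocateLexicon(entries=entries)


def save_lexicon(lex: CollocateLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, collocates in lex.entries.items():
            fh.write(f"{term}\t{','.join(collocates)}\n")


@dataclass(frozen=True)
class ExpandedSet:
    """A term set unioned with all collocates of its members (binary membership)."""

    owner: tuple[str, int]
    members: frozenset[str]


def expand(ts: TermSet, lex: CollocateLexicon) -> ExpandedSet:
    """members = terms ∪ collocates(term) for every term.  Monotone in the
    term set, and the identity when the lexicon knows none of the terms."""
    members = set(ts.terms)
    for term in ts.terms:
        members.update(lex.entries.get(term, ()))
    return ExpandedSet(owner=ts.owner, members=frozenset(members))
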