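"""Ochiai similarity between expanded column sets.

The Ochiai coefficient |A∩B| / sqrt(|A|·|B|) equals the cosine similarity of
the sets' binary indicator vectors over any vocabulary containing A∪B, which
is why it is the natural set form of cosine similarity for presence/absence
data.  For each pair of spreadsheets the coefficients are assembled into a
dense matrix (rows: columns of the first sheet, cols: columns of the second)
that the greedy matcher consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import ExpandedSet


def _members(x) -> frozenset:
    # Accept ExpandedSet or any plain set-like for convenience in tests.
    return x.members if isinstance(x, ExpandedSet) else frozenset(x)


def ochiai(a, b) -> float:
    """|a∩b| / sqrt(|a|·|b|), defined as 0.0 when either set is empty.

    The empty-set convention avoids 0/0 and makes blank columns unmergeable,
    the conservative choice.
    """
    sa, sb = _members(a), _members(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


@dataclass(frozen=True)
class SimilarityMatrix:
    """All pairwise Ochiai scores for one ordered pair of spreadsheets."""

    sheet_pair: tuple[str, str]
    scores: np.ndarray  # shape (n_cols_j, n_cols_k), entries in [0, 1]

    def __post_init__(self) -> None:
        if self.scores.ndim != 2:
            raise ValueError("similarity matrix must be 2-D")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("similarity scores must lie in [0, 1]")


def build_cs_matrix(
    sheet_j: Sequence[ExpandedSet], sheet_k: Sequence[ExpandedSet]
) -> SimilarityMatrix:
    """Dense similarity matrix between two sheets' expanded sets.

    Swapping the arguments transposes the result.  Column counts in practice
    are a few hundred at most, so dense storage is trivial.
    """
    if not sheet_j or not sheet_k:
        raise ValueError("both spreadsheets must contribute at least one column")
    scores = np.empty((len(sheet_j), len(sheet_k)), dtype=float)
    for x, a in enumerate(sheet_j):
        for y, b in enumerate(sheet_k):
            scores[x, y] = ochiai(a, b)
    return SimilarityMatrix(
        sheet_pair=(sheet_j[0].owner[0], sheet_k[0].owner[0]), scores=scores
    )
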