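"""Independent reference implementations used only to check the package.

These deliberately share no code with sheetmerge: the cosine oracle works on
explicit 0/1 vectors over the union vocabulary, and the greedy oracle
re-scans the full matrix with pure-Python loops each round.
"""

from __future__ import annotations

import numpy as np


def bitwise_cosine(a: set, b: set) -> float:
    """Cosine similarity of binary indicator vectors over the union vocabulary."""
    vocab = sorted(a | b)
    if not vocab:
        return 0.0
    va = np.array([1.0 if w in a else 0.0 for w in vocab])
    vb = np.array([1.0 if w in b else 0.0 for w in vocab])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(va @ vb / (na * nb))


def greedy_rescan(matrix, threshold: float):
    """Re-scan greedy reference: each round, scan every live cell for the
    maximum (first hit in row-major order wins ties), record the pair, and
    retire its row and column."""
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    alive_rows = list(range(n_rows))
    alive_cols = list(range(n_cols))
    pairs = []
    while alive_rows and alive_cols:
        best = None
        for r in alive_rows:
            for c in alive_cols:
                if best is None or matrix[r][c] > best[2]:
                    best = (r, c, matrix[r][c])
        r, c, s = best
        pairs.append((r, c, float(s), s >= threshold))
        alive_rows.remove(r)
        alive_cols.remove(c)
    return pairs
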