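"""Independent reference implementations used only to check the package.

These deliberately share no code with ``spacerviz``: the local aligner is a
tuple-valued dynamic program (no packed keys, no traceback) and the
reachability oracle is a dense Floyd-Warshall transitive closure.
"""

from __future__ import annotations

import numpy as np

MATCH = 5
MISMATCH = -4
GAP_OPEN = -12
GAP_EXTEND = -4

# value triple ordering: (score, columns, -gaps, matches), maximized
_MINUS_INF = (-(10**9), 0, 0, 0)


def oracle_local_align(a: str, b: str) -> tuple[int, int, int, int, int]:
    """Best local alignment of ``a`` vs ``b`` maximizing
    (score, columns, -gap_columns, matches) lexicographically.

    Returns (score, columns, mismatches, gaps, matches).  Plain Gotoh
    recursion over explicit tuples; O(n*m) but slow, for short sequences.
    """
    n, m = len(a), len(b)

    def add(v, ds, dc, dg, dm):
        return (v[0] + ds, v[1] + dc, v[2] - dg, v[3] + dm)

    zero = (0, 0, 0, 0)
    M = [[_MINUS_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_MINUS_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_MINUS_INF] * (m + 1) for _ in range(n + 1)]
    best = zero
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            hit = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            start = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], zero)
            M[i][j] = add(start, MATCH if hit else MISMATCH, 1, 0, 1 if hit else 0)
            X[i][j] = max(
                add(M[i - 1][j], GAP_OPEN, 1, 1, 0),
                add(X[i - 1][j], GAP_EXTEND, 1, 1, 0),
            )
            Y[i][j] = max(
                add(M[i][j - 1], GAP_OPEN, 1, 1, 0),
                add(Y[i][j - 1], GAP_EXTEND, 1, 1, 0),
            )
            if M[i][j] > best:
                best = M[i][j]
    score, cols, neg_gaps, matches = best
    gaps = -neg_gaps
    mismatches = cols - gaps - matches
    return score, cols, mismatches, gaps, matches


def oracle_adjusted(a: str, b: str) -> int:
    """Reference symmetric adjusted-mismatch score (min over directions)."""
    *_ignored, matches = oracle_local_align(a, b)
    return min(len(a), len(b)) - matches


def oracle_components(n_nodes: int, edges: list[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components via boolean Floyd-Warshall reachability."""
    reach = np.eye(n_nodes, dtype=bool)
    for i, j in edges:
        reach[i, j] = reach[j, i] = True
    for k in range(n_nodes):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    comps = []
    seen: set[int] = set()
    for i in range(n_nodes):
        if i not in seen:
            comp = frozenset(np.flatnonzero(reach[i]).tolist())
            seen |= comp
            comps.append(comp)
    return comps
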