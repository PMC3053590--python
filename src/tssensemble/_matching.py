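"""Greedy one-to-one matching of genomic positions under a distance tolerance.

Shared by the overlap (intersection-over-union) measure and by the
point-call evaluators.  Candidate pairs within tolerance are matched
shortest-distance-first, each position used at most once; ties are broken
by (distance, left position, right position) for reproducibility.

Greedy matching equals maximum-cardinality matching whenever each
position has at most one candidate partner — in particular when both
input sets are pre-clustered at radius >= 2 * tolerance, the regime the
overlap analysis operates in.  On adversarial un-clustered inputs it can
fall below the optimum (never above); see the tests for a constructed
example.
"""

from __future__ import annotations

import numpy as np


def greedy_match_pairs(pos_a, lo_a, hi_a, pos_b):
    """Match positions of ``a`` to positions of ``b`` on one chromosome.

    ``b[j]`` is a candidate for ``a[i]`` iff ``lo_a[i] <= pos_b[j] <= hi_a[i]``
    (an asymmetric, per-``a`` acceptance window).  Returns a list of
    (i, j) index pairs.
    """
    pos_a = np.asarray(pos_a, dtype=np.int64)
    pos_b = np.asarray(pos_b, dtype=np.int64)
    if pos_a.size == 0 or pos_b.size == 0:
        return []
    order_b = np.argsort(pos_b, kind="stable")
    sorted_b = pos_b[order_b]
    cand = []  # (dist, pos_a, pos_b, i, j)
    for i in range(pos_a.size):
        lo = np.searchsorted(sorted_b, lo_a[i], side="left")
        hi = np.searchsorted(sorted_b, hi_a[i], side="right")
        for k in range(lo, hi):
            j = order_b[k]
            cand.append((abs(int(pos_a[i]) - int(pos_b[j])), int(pos_a[i]), int(pos_b[j]), i, int(j)))
    cand.sort()
    used_a = np.zeros(pos_a.size, dtype=bool)
    used_b = np.zeros(pos_b.size, dtype=bool)
    pairs = []
    for _, _, _, i, j in cand:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
    return pairs


def greedy_match_count(pos_a, pos_b, tol: int) -> int:
    """Number of one-to-one matches within a symmetric tolerance."""
    pos_a = np.asarray(pos_a, dtype=np.int64)
    lo = pos_a - tol
    hi = pos_a + tol
    return len(greedy_match_pairs(pos_a, lo, hi, pos_b))
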