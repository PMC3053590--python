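"""Bundled reference data.

Published pairwise intersection-over-union overlaps (1000 bp tolerance)
between whole-genome promoter prediction sets of seven programs
(N-SCAN, FirstEF, Eponine, ProSOM, EP3, ARTS, Profisi), measured on human
assembly hg17 after deduplication to roughly 20,000 predictions per
program.  Three matrices are provided: overlaps over all predictions,
over true positives only, and over false positives only (true positive =
within 1000 bp of the 5' end of a RefSeq first exon).

These small published summaries serve as worked inputs for the
overlap-matrix utilities; recomputing them from scratch would require the
original whole-genome prediction files.
"""

from __future__ import annotations

import numpy as np

from .diversity import OverlapMatrix

__all__ = [
    "PROGRAM_NAMES",
    "published_overlap_all",
    "published_overlap_true_positives",
    "published_overlap_false_positives",
]

PROGRAM_NAMES = ["N-SCAN", "FirstEF", "Eponine", "ProSOM", "EP3", "ARTS", "Profisi"]

# Row-wise lower triangles (including the unit diagonal), one row per program.
_ALL = [
    [1.000],
    [0.424, 1.000],
    [0.442, 0.440, 1.000],
    [0.212, 0.284, 0.256, 1.000],
    [0.209, 0.317, 0.244, 0.575, 1.000],
    [0.308, 0.314, 0.319, 0.161, 0.162, 1.000],
    [0.319, 0.504, 0.360, 0.255, 0.290, 0.247, 1.000],
]

_TRUE_POSITIVES = [
    [1.000],
    [0.740, 1.000],
    [0.569, 0.624, 1.000],
    [0.384, 0.432, 0.436, 1.000],
    [0.413, 0.473, 0.457, 0.704, 1.000],
    [0.626, 0.688, 0.612, 0.401, 0.428, 1.000],
    [0.579, 0.661, 0.580, 0.414, 0.445, 0.581, 1.000],
]

_FALSE_POSITIVES = [
    [1.000],
    [0.218, 1.000],
    [0.294, 0.315, 1.000],
    [0.109, 0.210, 0.164, 1.000],
    [0.103, 0.244, 0.149, 0.523, 1.000],
    [0.136, 0.163, 0.174, 0.082, 0.080, 1.000],
    [0.168, 0.416, 0.241, 0.195, 0.232, 0.131, 1.000],
]


def _symmetrize(rows) -> OverlapMatrix:
    n = len(rows)
    m = np.zeros((n, n))
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return OverlapMatrix(list(PROGRAM_NAMES), m)


def published_overlap_all() -> OverlapMatrix:
    """Overlaps between all predictions of the seven programs."""
    return _symmetrize(_ALL)


def published_overlap_true_positives() -> OverlapMatrix:
    """Overlaps restricted to true-positive predictions."""
    return _symmetrize(_TRUE_POSITIVES)


def published_overlap_false_positives() -> OverlapMatrix:
    """Overlaps restricted to false-positive predictions."""
    return _symmetrize(_FALSE_POSITIVES)
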