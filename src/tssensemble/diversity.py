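"""Agreement between promoter prediction sets.

Whole-genome predictors disagree substantially; this module quantifies
that heterogeneity, which is what makes an ensemble worthwhile.  Sets are
first deduplicated by greedy highest-score clustering, then compared by
tolerance-aware intersection-over-union, optionally after stratifying
predictions into true/false positives against a reference TSS annotation.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._matching import greedy_match_count
from .tracks import PointPredictionSet, ScoreTrack

__all__ = [
    "ReferenceTSS",
    "OverlapMatrix",
    "cluster_points",
    "threshold_track_to_points",
    "overlap",
    "stratify",
    "overlap_matrix",
    "mean_offdiagonal",
]


@dataclass
class ReferenceTSS:
    """Reference transcription start sites: (chromosome, 5' position, strand)."""

    records: pd.DataFrame

    COLUMNS = ("chrom", "pos", "strand")

    def __post_init__(self):
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        df["pos"] = df["pos"].astype(int)
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"reference strand must be +/-, got {df.loc[bad, 'strand'].iloc[0]!r}")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, chrom, pos, strand):
        return cls(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand}))

    @classmethod
    def from_bed(cls, path):
        """Strand-aware 5' ends of BED intervals: start for +, end-1 for -."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: stranded BED6 required")
                start, end, strand = int(f[1]), int(f[2]), f[5]
                pos = start if strand == "+" else end - 1
                rows.append((f[0], pos, strand))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def __len__(self):
        return len(self.records)

    def positions_for(self, chrom: str) -> np.ndarray:
        return self.records.loc[self.records["chrom"] == chrom, "pos"].to_numpy()


@dataclass
class OverlapMatrix:
    """Symmetric matrix of pairwise intersection-over-union overlaps."""

    names: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(v, v.T):
            raise ValueError("overlap matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("overlap matrix diagonal must be 1")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("overlaps must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def cluster_points(points: PointPredictionSet, radius: int) -> PointPredictionSet:
    """Greedy highest-score deduplication of a prediction set.

    Repeatedly keep the highest-scoring remaining record and discard all
    records on the same chromosome within ``radius`` bp of it.  Score ties
    are resolved in favour of the leftmost record (chromosome, position
    ascending).  The result is sorted by coordinate.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    df = points.records.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    kept_rows = []
    kept_by_chrom: dict = {}
    for row in df.itertuples():
        kept = kept_by_chrom.setdefault(row.chrom, [])
        i = bisect_left(kept, row.pos)
        near = (i > 0 and row.pos - kept[i - 1] <= radius) or (
            i < len(kept) and kept[i] - row.pos <= radius
        )
        if not near:
            insort(kept, row.pos)
            kept_rows.append(row.Index)
    out = points.records.loc[kept_rows]
    return PointPredictionSet(out, name=points.name).sort_canonical()


def threshold_track_to_points(
    track: ScoreTrack, target_count: int, radius: int
) -> PointPredictionSet:
    """Reduce a continuous track to ~``target_count`` scored point calls.

    Local maxima of the track are clustered greedily with ``radius``, then
    a score threshold is chosen over the surviving peak scores so the
    retained count is as close as possible to ``target_count`` (ties
    resolved toward the larger count).
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    peaks = _local_maxima(track)
    if len(peaks) == 0:
        if track.max() > 0:
            warnings.warn("track has no local maxima (constant?); using grid positions")
            peaks = _grid_points(track, radius, target_count)
        else:
            warnings.warn("all-zero track; returning empty point set")
            return PointPredictionSet.from_arrays([], [], name=track.name)
    clustered = cluster_points(peaks, radius)
    scores = np.sort(clustered.records["score"].to_numpy())[::-1]
    if len(scores) <= target_count:
        return clustered
    # count(threshold=scores[k-1]) == k for distinct scores; pick k closest
    # to the target, ties toward the larger count.
    counts = np.arange(1, len(scores) + 1)
    best_k = counts[np.lexsort((-counts, np.abs(counts - target_count)))][0]
    thr = scores[best_k - 1]
    keep = clustered.records["score"] >= thr
    return PointPredictionSet(clustered.records.loc[keep], name=track.name).sort_canonical()


def _local_maxima(track: ScoreTrack) -> PointPredictionSet:
    """Positive strict local maxima; equal-value plateaus report their center."""
    chroms, poss, scores = [], [], []
    for c in track.layout.names:
        v = track.values[c]
        if len(v) < 2:
            continue
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        rv = v[starts]
        if len(rv) < 2:
            continue  # constant chromosome: no local maximum
        ok = np.zeros(len(rv), dtype=bool)
        ok[1:-1] = (rv[1:-1] > rv[:-2]) & (rv[1:-1] > rv[2:])
        ok &= rv > 0
        idx = np.flatnonzero(ok)
        centers = (starts[idx] + ends[idx] - 1) // 2
        chroms.extend([c] * len(idx))
        poss.extend((centers * track.step).tolist())
        scores.extend(rv[idx].tolist())
    return PointPredictionSet.from_arrays(chroms, poss, score=scores, name=track.name)


def _grid_points(track: ScoreTrack, radius: int, target_count: int) -> PointPredictionSet:
    spacing = max(radius + track.step, track.step)
    chroms, poss, scores = [], [], []
    for c in track.layout.names:
        grid = np.arange(0, track.layout.length(c), spacing)
        chroms.extend([c] * len(grid))
        poss.extend(grid.tolist())
        scores.extend(track.values[c][grid // track.step].tolist())
        if len(poss) >= target_count:
            break
    return PointPredictionSet.from_arrays(
        chroms[:target_count], poss[:target_count], score=scores[:target_count], name=track.name
    )


def overlap(a: PointPredictionSet, b: PointPredictionSet, tol: int) -> float:
    """Intersection-over-union of two (deduplicated) prediction sets.

    Positions on the same chromosome within ``tol`` bp are matched
    one-to-one, shortest distances first; the overlap is
    ``|matches| / (|a| + |b| - |matches|)``.  Two empty sets overlap 0 by
    convention.
    """
    if len(a) == 0 and len(b) == 0:
        return 0.0
    chroms = sorted(set(a.records["chrom"]) | set(b.records["chrom"]))
    m = sum(
        greedy_match_count(a.positions_for(c), b.positions_for(c), tol) for c in chroms
    )
    return m / (len(a) + len(b) - m)


def stratify(
    points: PointPredictionSet, ref: ReferenceTSS, tol: int
) -> tuple:
    """Partition predictions into true and false positives.

    A prediction is a true positive iff some reference 5' end on the same
    chromosome lies within ``tol`` bp (strand is ignored; distance is what
    counts).  The partition is exhaustive and disjoint.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    is_tp = np.zeros(len(points), dtype=bool)
    for c in points.records["chrom"].unique():
        mask = (points.records["chrom"] == c).to_numpy()
        pos = points.records.loc[mask, "pos"].to_numpy()
        rpos = np.sort(ref.positions_for(c))
        if rpos.size == 0:
            continue
        i = np.searchsorted(rpos, pos)
        left = np.where(i > 0, pos - rpos[np.maximum(i - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(i < rpos.size, rpos[np.minimum(i, rpos.size - 1)] - pos, np.iinfo(np.int64).max)
        is_tp[mask] = np.minimum(left, right) <= tol
    tp = PointPredictionSet(points.records.loc[is_tp], name=f"{points.name}.TP")
    fp = PointPredictionSet(points.records.loc[~is_tp], name=f"{points.name}.FP")
    return tp, fp


def overlap_matrix(sets: list, tol: int, names: list | None = None) -> OverlapMatrix:
    """Pairwise intersection-over-union matrix for >=2 prediction sets."""
    if len(sets) < 2:
        raise ValueError("need at least two prediction sets")
    if names is None:
        names = [s.name or f"set{i}" for i, s in enumerate(sets)]
    n = len(sets)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = overlap(sets[i], sets[j], tol)
    return OverlapMatrix(names, m)


def mean_offdiagonal(m: OverlapMatrix) -> float:
    """Arithmetic mean of the strictly-below-diagonal overlap entries."""
    n = len(m.names)
    if n < 2:
        raise ValueError("need at least a 2x2 matrix")
    idx = np.tril_indices(n, k=-1)
    return float(m.values[idx].mean())
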