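"""Discrete point calls from continuous promoter-activity tracks.

Older evaluation schemes score discrete TSS predictions, so continuous
tracks are reduced to points by thresholding (drop everything below a
score level) followed by greedy highest-score clustering (keep the best
position, discard everything within a radius, repeat).  Both parameters
can be grid-searched against a reference annotation under a strand-aware
asymmetric distance tolerance (e.g. 200 bp upstream / 100 bp downstream
of the annotated TSS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._matching import greedy_match_pairs
from .diversity import ReferenceTSS, cluster_points
from .tracks import PointPredictionSet, ScoreTrack

__all__ = [
    "threshold_and_cluster",
    "match_asymmetric",
    "calibrate_pointcalls",
    "restrict_to_regions",
]


def threshold_and_cluster(track: ScoreTrack, threshold: float, radius: int) -> PointPredictionSet:
    """Point calls: positions scoring >= threshold, greedily declustered."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    chroms, poss, scores = [], [], []
    for c in track.layout.names:
        v = track.values[c]
        idx = np.flatnonzero((v >= threshold) & (v > 0))
        chroms.extend([c] * len(idx))
        poss.extend((idx * track.step).tolist())
        scores.extend(v[idx].tolist())
    points = PointPredictionSet.from_arrays(chroms, poss, score=scores, name=track.name)
    return cluster_points(points, radius)


def match_asymmetric(points: PointPredictionSet, ref: ReferenceTSS, up: int, down: int) -> tuple:
    """One-to-one strand-aware matching with asymmetric tolerance.

    A prediction matches a + strand TSS at t if it lies in
    ``[t - up, t + down]`` (the window mirrored for - strand), nearest
    distances matched first, each prediction and each TSS used at most
    once.  Returns (TP, FP, FN) counts.
    """
    if up < 0 or down < 0:
        raise ValueError("tolerances must be >= 0")
    tp = 0
    for chrom in ref.records["chrom"].unique():
        sub = ref.records[ref.records["chrom"] == chrom]
        tpos = sub["pos"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        lo = np.where(plus, tpos - up, tpos - down)
        hi = np.where(plus, tpos + down, tpos + up)
        ppos = points.positions_for(str(chrom))
        tp += len(greedy_match_pairs(tpos, lo, hi, ppos))
    return tp, len(points) - tp, len(ref) - tp


def restrict_to_regions(points: PointPredictionSet, regions: list) -> PointPredictionSet:
    """Discard predictions outside the evaluated (half-open) regions."""
    keep = np.zeros(len(points), dtype=bool)
    for chrom, start, end in regions:
        m = (points.records["chrom"] == chrom).to_numpy()
        pos = points.records["pos"].to_numpy()
        keep |= m & (pos >= start) & (pos < end)
    return PointPredictionSet(points.records.loc[keep], name=points.name)


def calibrate_pointcalls(
    track: ScoreTrack,
    ref: ReferenceTSS,
    thresholds,
    radii,
    up: int,
    down: int,
    regions: list | None = None,
) -> tuple:
    """Grid search (threshold, radius) maximising F1 against the reference.

    Returns ``((threshold, radius), f1)``.  Ties prefer the larger
    threshold, then the smaller radius.  If ``regions`` is given,
    predictions outside them are discarded before counting.
    """
    thresholds = sorted(set(thresholds))
    radii = sorted(set(radii))
    if not thresholds or not radii:
        raise ValueError("grids must be non-empty")
    best = None
    for radius in radii:
        for threshold in thresholds:
            calls = threshold_and_cluster(track, threshold, radius)
            if regions is not None:
                calls = restrict_to_regions(calls, regions)
            tp, fp, fn = match_asymmetric(calls, ref, up, down)
            f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            key = (f1, threshold, -radius)
            if best is None or key > best[0]:
                best = (key, (threshold, radius), f1)
    return best[1], best[2]
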