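"""Evaluation of promoter-activity scores against reference TSS.

Sensitivity here is the fraction of reference TSS whose neighbourhood
(within a bp tolerance) reaches a score threshold; specificity is the
fraction of designated negative positions scoring below the threshold.
Sweeping the threshold yields a sensitivity-specificity curve with an
AUC summary.  Two threshold-free protocol scores are provided for
CAGE-tag style truth sets — distance-based one-to-one matching and
fixed-bin classification — each scalarised as the maximum over
thresholds of the harmonic mean of sensitivity and positive predictive
value, plus the harmonic-mean aggregation that condenses four protocol
scores into a single figure of overall predictive power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._matching import greedy_match_pairs
from .diversity import ReferenceTSS, threshold_track_to_points
from .tracks import PointPredictionSet, ScoreTrack

__all__ = [
    "EvaluationCurve",
    "sens_spec_curve",
    "score_positions",
    "background_positions",
    "protocol_distance",
    "protocol_bin",
    "ppp_score",
]


@dataclass
class EvaluationCurve:
    """Ordered (threshold, sensitivity, specificity) triples."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, float)
        s = np.asarray(self.sensitivity, float)
        p = np.asarray(self.specificity, float)
        if not (len(t) == len(s) == len(p)):
            raise ValueError("curve arrays must have equal length")
        order = np.argsort(t, kind="mergesort")
        t, s, p = t[order], s[order], p[order]
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("sensitivity must be non-increasing in the threshold")
        for a in (s, p):
            if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
                raise ValueError("rates must lie in [0, 1]")
        self.thresholds, self.sensitivity, self.specificity = t, s, p

    def auc(self) -> float:
        """Area under sensitivity vs (1 - specificity), endpoints included."""
        fpr = 1.0 - self.specificity
        order = np.lexsort((self.sensitivity, fpr))
        x = np.concatenate(([0.0], fpr[order], [1.0]))
        y = np.concatenate(([0.0], self.sensitivity[order], [1.0]))
        return float(np.trapezoid(y, x))

    def sensitivity_at_specificity(self, grid: np.ndarray) -> np.ndarray:
        """Monotone interpolation of sensitivity on a specificity grid."""
        order = np.argsort(self.specificity, kind="mergesort")
        sp = self.specificity[order]
        se = self.sensitivity[order]
        # enforce a proper step function: best sensitivity at >= each spec
        se = np.maximum.accumulate(se[::-1])[::-1]
        return np.interp(grid, sp, se, left=1.0, right=0.0 if sp.max() < 1 else se[-1])

    def threshold_at_specificity(self, spec: float) -> float:
        """Smallest threshold whose specificity reaches ``spec``."""
        ok = self.specificity >= spec
        if not ok.any():
            return float(self.thresholds[-1])
        return float(self.thresholds[ok][0])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tsensitivity\tspecificity\n")
            for t, s, p in zip(self.thresholds, self.sensitivity, self.specificity):
                fh.write(f"{t:g}\t{s:.6f}\t{p:.6f}\n")


def _window_max(track: ScoreTrack, chroms, positions, tol: int) -> np.ndarray:
    """Best track score within ±tol bp of each (chrom, pos)."""
    out = np.empty(len(positions))
    step = track.step
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        v = track.values[chrom]
        lo = max(0, (pos - tol) // step)
        hi = min(len(v), (pos + tol) // step + 1)
        out[i] = v[lo:hi].max() if hi > lo else 0.0
    return out


def score_positions(track: ScoreTrack, ref: ReferenceTSS, tol: int) -> np.ndarray:
    """Best track score within ±tol of each reference 5' end."""
    df = ref.records
    return _window_max(track, df["chrom"].tolist(), df["pos"].tolist(), tol)


def background_positions(
    layout, ref: ReferenceTSS, min_dist: int = 1000, spacing: int = 500, max_n: int = 20000, seed: int = 0
) -> list:
    """Deterministic grid of negative positions >= min_dist from any TSS.

    A regular grid (every ``spacing`` bp) is filtered against the
    reference and, if needed, subsampled to ``max_n`` with a seeded RNG.
    """
    picks = []
    for chrom in layout.names:
        grid = np.arange(0, layout.length(chrom), spacing)
        tss = np.sort(ref.positions_for(chrom))
        if tss.size:
            i = np.searchsorted(tss, grid)
            left = np.where(i > 0, grid - tss[np.maximum(i - 1, 0)], np.iinfo(np.int64).max)
            right = np.where(i < tss.size, tss[np.minimum(i, tss.size - 1)] - grid, np.iinfo(np.int64).max)
            grid = grid[np.minimum(left, right) >= min_dist]
        picks.extend((chrom, int(p)) for p in grid)
    if len(picks) > max_n:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(picks), size=max_n, replace=False))
        picks = [picks[i] for i in idx]
    return picks


def _as_score_arrays(scores, ref, tol, negatives):
    if isinstance(scores, ScoreTrack):
        pos_scores = score_positions(scores, ref, tol)
        neg_scores = _window_max(
            scores, [c for c, _ in negatives], [p for _, p in negatives], tol
        )
    elif isinstance(scores, PointPredictionSet):
        track_like = scores
        pos_scores = np.zeros(len(ref))
        for i, r in enumerate(ref.records.itertuples(index=False)):
            pos = track_like.positions_for(r.chrom)
            sc = track_like.records.loc[track_like.records["chrom"] == r.chrom, "score"].to_numpy()
            near = np.abs(pos - r.pos) <= tol
            pos_scores[i] = sc[near].max() if near.any() else 0.0
        neg_scores = np.zeros(len(negatives))
        for i, (c, p) in enumerate(negatives):
            pos = track_like.positions_for(c)
            sc = track_like.records.loc[track_like.records["chrom"] == c, "score"].to_numpy()
            near = np.abs(pos - p) <= tol
            neg_scores[i] = sc[near].max() if near.any() else 0.0
    else:
        raise TypeError("scores must be a ScoreTrack or PointPredictionSet")
    return pos_scores, neg_scores


def sens_spec_curve(scores, ref: ReferenceTSS, tol: int, negatives: list) -> EvaluationCurve:
    """Sensitivity-specificity curve of a score track over all thresholds.

    At threshold t: sensitivity = fraction of reference TSS with a score
    >= t within ``tol`` bp; specificity = fraction of ``negatives``
    (a list of (chrom, pos)) whose best score within the same ±tol
    window is < t — positives and negatives are judged symmetrically.
    """
    if len(ref) == 0:
        raise ValueError("reference TSS set is empty")
    if not negatives:
        raise ValueError("negative positions are required for specificity")
    pos_scores, neg_scores = _as_score_arrays(scores, ref, tol, negatives)
    thresholds = np.unique(np.concatenate((pos_scores, neg_scores)))
    if thresholds.size < 2:
        raise ValueError("degenerate scores: no threshold variation")
    # include a threshold above the max so (sens 0, spec 1) is on the curve
    thresholds = np.concatenate((thresholds, [thresholds[-1] + 1.0]))
    pos_sorted = np.sort(pos_scores)
    neg_sorted = np.sort(neg_scores)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / len(pos_sorted)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg_sorted)
    return EvaluationCurve(thresholds, sens, spec)


def _max_f(call_scores_per_tag: np.ndarray, call_scores: np.ndarray, n_tags: int) -> float:
    """Max over thresholds of harmonic mean(sensitivity, PPV).

    ``call_scores_per_tag``: best matched-call score per tag (-inf if
    unmatched); ``call_scores``: scores of all calls.
    """
    if call_scores.size == 0 or n_tags == 0:
        return 0.0
    best = 0.0
    for t in np.unique(call_scores):
        tp = int((call_scores_per_tag >= t).sum())
        n_calls = int((call_scores >= t).sum())
        if tp == 0 or n_calls == 0:
            continue
        sens = tp / n_tags
        ppv = tp / n_calls
        f = 2 * sens * ppv / (sens + ppv)
        best = max(best, f)
    return best


def protocol_distance(
    track: ScoreTrack, tags: ReferenceTSS, max_dist: int = 500, radius: int | None = None
) -> float:
    """Distance-based protocol score in [0, 1].

    The track is reduced to point calls (local maxima, greedily clustered
    at ``radius``, default ``max_dist``); calls are matched one-to-one to
    tags within ``max_dist`` bp, nearest first.  The score is the maximum
    over call-score thresholds of the harmonic mean of sensitivity and
    PPV.  Depends only on the ranking of track scores.
    """
    if len(tags) == 0:
        raise ValueError("tag set is empty")
    radius = max_dist if radius is None else radius
    calls = threshold_track_to_points(track, target_count=max(1, 4 * len(tags)), radius=radius) \
        if track.max() > 0 else PointPredictionSet.from_arrays([], [])
    if len(calls) == 0:
        return 0.0
    per_tag = np.full(len(tags), -np.inf)
    call_scores_all = []
    offset = 0
    for chrom in {c for c in tags.records["chrom"]} | set(calls.records["chrom"]):
        tmask = (tags.records["chrom"] == chrom).to_numpy()
        tpos = tags.records.loc[tmask, "pos"].to_numpy()
        cmask = (calls.records["chrom"] == chrom).to_numpy()
        cpos = calls.records.loc[cmask, "pos"].to_numpy()
        cscore = calls.records.loc[cmask, "score"].to_numpy()
        call_scores_all.append(cscore)
        if tpos.size and cpos.size:
            pairs = greedy_match_pairs(tpos, tpos - max_dist, tpos + max_dist, cpos)
            tidx = np.flatnonzero(tmask)
            for i, j in pairs:
                per_tag[tidx[i]] = cscore[j]
    call_scores = np.concatenate(call_scores_all) if call_scores_all else np.array([])
    return _max_f(per_tag, call_scores, len(tags))


def protocol_bin(track: ScoreTrack, tags: ReferenceTSS, bin: int = 500) -> float:
    """Bin-based protocol score in [0, 1].

    The genome is partitioned into fixed ``bin``-bp windows; each bin is
    scored by its maximum track value and labelled by whether it contains
    a tag.  The score is the maximum over thresholds of the harmonic mean
    of bin-level sensitivity and PPV.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if len(tags) == 0:
        raise ValueError("tag set is empty")
    bin_scores, bin_has_tag = [], []
    for chrom in track.layout.names:
        v = track.values[chrom]
        factor = -(-bin // track.step)
        n_out = -(-len(v) // factor)
        pad = np.full(n_out * factor, -np.inf)
        pad[: len(v)] = v
        bs = pad.reshape(n_out, factor).max(axis=1)
        tag_bins = np.zeros(n_out, dtype=bool)
        tpos = tags.positions_for(chrom)
        tag_bins[np.minimum(tpos // (factor * track.step), n_out - 1)] = True
        bin_scores.append(bs)
        bin_has_tag.append(tag_bins)
    scores = np.concatenate(bin_scores)
    has_tag = np.concatenate(bin_has_tag)
    if not has_tag.any() or scores.max() <= 0:
        return 0.0
    best = 0.0
    for t in np.unique(scores[scores > 0]):
        called = scores >= t
        tp = int((called & has_tag).sum())
        if tp == 0:
            continue
        sens = tp / int(has_tag.sum())
        ppv = tp / int(called.sum())
        best = max(best, 2 * sens * ppv / (sens + ppv))
    return best


def ppp_score(s1a: float, s1b: float, s2a: float, s2b: float) -> float:
    """Harmonic mean of four protocol scores (overall predictive power)."""
    scores = (s1a, s1b, s2a, s2b)
    if any(s <= 0 for s in scores):
        raise ValueError("all protocol scores must be > 0")
    return 4.0 / sum(1.0 / s for s in scores)
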