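"""Information-gain feature ranking.

Each feature column is discretized by Fayyad–Irani MDL supervised
binning (recursive entropy minimisation with the minimum-description-
length stopping rule), and the information gain of the resulting
partition about the class labels is reported in bits.  Because the
discretization depends only on the ordering of feature values, the gain
is invariant under strictly monotone transforms of a column.  Columns for
which no cut point passes the MDL test get gain 0.

The top-k features by gain define the "reduced" feature set of the
two-level ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trainset import FeatureMatrix

__all__ = ["FeatureRanking", "info_gain", "rank_features", "select_top"]


@dataclass
class FeatureRanking:
    """Features ordered by decreasing information gain (bits)."""

    entries: list  # (feature name, gain)

    def __post_init__(self):
        gains = [g for _, g in self.entries]
        if any(g < -1e-12 for g in gains):
            raise ValueError("information gain cannot be negative")
        if any(g1 < g2 - 1e-12 for g1, g2 in zip(gains, gains[1:])):
            raise ValueError("ranking must be sorted by decreasing gain")

    @property
    def names(self) -> list:
        return [n for n, _ in self.entries]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("score\tfeature\n")
            for n, g in self.entries:
                fh.write(f"{g:.3f}\t{n}\n")


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k)


def _best_cut(y_sorted: np.ndarray, k: int):
    """Best binary split of a label sequence ordered by feature value.

    Returns (index, weighted conditional entropy) where the split is
    between positions index-1 and index, or None if no candidate exists.
    Candidate boundaries are evaluated exhaustively; splitting inside a
    run of equal labels can never be optimal, but equal feature values are
    handled by the caller (cuts are only allowed between distinct values).
    """
    n = len(y_sorted)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_sorted] = 1.0
    left = np.cumsum(onehot, axis=0)  # left[i] = counts of y[:i+1]
    total = left[-1]
    ent_left = np.empty(n - 1)
    ent_right = np.empty(n - 1)
    for i in range(n - 1):
        ent_left[i] = _entropy(left[i])
        ent_right[i] = _entropy(total - left[i])
    w = np.arange(1, n) / n
    cond = w * ent_left + (1 - w) * ent_right
    return cond


def _mdlp_partition(x: np.ndarray, y: np.ndarray, k: int, lo: int, hi: int, cuts: list):
    """Recursively accept MDL-justified cut points on x[lo:hi] (x sorted)."""
    n = hi - lo
    if n < 2:
        return
    ys = y[lo:hi]
    xs = x[lo:hi]
    allowed = xs[1:] != xs[:-1]  # cut only between distinct feature values
    if not allowed.any():
        return
    cond = _best_cut(ys, k)
    cond = np.where(allowed, cond, np.inf)
    i = int(np.argmin(cond))
    ent_s = _entropy(_class_counts(ys, k))
    gain = ent_s - cond[i]
    # MDL acceptance (Fayyad & Irani): gain must exceed the per-example
    # cost of coding the cut point and the extra class structure.
    left, right = ys[: i + 1], ys[i + 1 :]
    k_s = len(np.unique(ys))
    k1, k2 = len(np.unique(left)), len(np.unique(right))
    delta = np.log2(3**k_s - 2) - (
        k_s * ent_s - k1 * _entropy(_class_counts(left, k)) - k2 * _entropy(_class_counts(right, k))
    )
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cuts.append(lo + i + 1)
    _mdlp_partition(x, y, k, lo, lo + i + 1, cuts)
    _mdlp_partition(x, y, k, lo + i + 1, hi, cuts)


def mdlp_bin_edges(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Accepted MDLP cut values (midpoints between adjacent distinct values)."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = np.asarray(x, float)[order], np.asarray(y)[order]
    classes, yi = np.unique(ys, return_inverse=True)
    cuts: list = []
    _mdlp_partition(xs, yi, len(classes), 0, len(xs), cuts)
    return np.array(sorted((xs[c - 1] + xs[c]) / 2.0 for c in cuts))


def info_gain(feature: np.ndarray, labels: np.ndarray) -> float:
    """Information gain (bits) of an MDLP-discretized feature about the labels.

    ``H(labels) - sum_bins p(bin) * H(labels | bin)``.  Constant labels
    (a single class) yield 0 with a warning; features with no accepted
    cut point yield 0.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if len(feature) != len(labels) or len(feature) < 2:
        raise ValueError("need >= 2 examples with matching labels")
    classes, yi = np.unique(labels, return_inverse=True)
    k = len(classes)
    if k < 2:
        warnings.warn("labels are constant; information gain is 0")
        return 0.0
    edges = mdlp_bin_edges(feature, labels)
    if edges.size == 0:
        return 0.0
    bins = np.searchsorted(edges, feature, side="left")
    h = _entropy(_class_counts(yi, k))
    cond = 0.0
    n = len(labels)
    for b in np.unique(bins):
        m = bins == b
        cond += (m.sum() / n) * _entropy(_class_counts(yi[m], k))
    return max(0.0, h - cond)


def rank_features(m: FeatureMatrix) -> FeatureRanking:
    """Rank all columns by information gain, ties broken by column order."""
    gains = [(name, info_gain(m.data[name].to_numpy(), m.labels)) for name in m.feature_names]
    order = sorted(range(len(gains)), key=lambda i: (-gains[i][1], i))
    return FeatureRanking([gains[i] for i in order])


def select_top(r: FeatureRanking, k: int) -> list:
    """Names of the k highest-gain features (the reduced feature set)."""
    if not (1 <= k <= len(r.entries)):
        raise ValueError(f"k must be in [1, {len(r.entries)}]")
    return r.names[:k]
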