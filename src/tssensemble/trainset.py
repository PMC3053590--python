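"""Labelled feature matrices for classifier training.

Positive examples are annotated TSS positions falling inside designated
training regions; negatives are uniform random positions in the same
regions, rejected when they fall within a minimum distance of any TSS
(default 1000 bp) or duplicate an earlier pick.  Feature values are read
off normalized score tracks at each example position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import ReferenceTSS
from .tracks import ScoreTrack

__all__ = ["FeatureMatrix", "sample_positives", "sample_negatives", "extract_features"]

POSITIVE, NEGATIVE = "promoter", "non-promoter"


@dataclass
class FeatureMatrix:
    """Examples x features table with class labels and genomic positions."""

    data: pd.DataFrame  # columns = feature names, values in [0, 1]
    labels: np.ndarray  # boolean, True = promoter
    positions: list  # (chrom, pos) per row
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.data) != len(self.labels) or len(self.data) != len(self.positions):
            raise ValueError("rows, labels and positions must have equal length")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate example positions")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("non-finite feature values")

    @property
    def feature_names(self) -> list:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.astype(int)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, features: list) -> "FeatureMatrix":
        return FeatureMatrix(self.data[list(features)], self.labels, self.positions, self.meta)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "chrom", [c for c, _ in self.positions])
        df.insert(1, "pos", [p for _, p in self.positions])
        df["label"] = np.where(self.labels, POSITIVE, NEGATIVE)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = (df.pop("label") == POSITIVE).to_numpy()
        positions = list(zip(df.pop("chrom"), df.pop("pos").astype(int)))
        return cls(df, labels, positions)


def _check_regions(regions):
    by_chrom: dict = {}
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError(f"empty region {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions on {chrom}")
    return by_chrom


def sample_positives(ref: ReferenceTSS, regions: list) -> list:
    """All reference TSS positions lying inside the (half-open) regions."""
    by_chrom = _check_regions(regions)
    out = []
    for r in ref.records.itertuples(index=False):
        for start, end in by_chrom.get(r.chrom, []):
            if start <= r.pos < end:
                out.append((r.chrom, int(r.pos)))
                break
    return out


def sample_negatives(
    ref: ReferenceTSS,
    regions: list,
    ratio: int = 5,
    min_dist: int = 1000,
    seed: int = 0,
) -> list:
    """Uniform random non-promoter positions within the training regions.

    Draws ``ratio`` times as many positions as there are reference TSS in
    the regions, rejecting any draw within ``min_dist`` bp of a TSS or
    duplicating an earlier pick.  Deterministic for a fixed seed.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    n_pos = len(sample_positives(ref, regions))
    n_needed = ratio * n_pos
    if n_needed == 0:
        return []
    regions = sorted(regions)
    lens = np.array([end - start for _, start, end in regions], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lens)))
    total = int(cum[-1])
    tss_by_chrom = {
        c: np.sort(ref.positions_for(c)) for c in {chrom for chrom, _, _ in regions}
    }
    rng = np.random.default_rng(seed)
    picked: list = []
    seen: set = set()
    attempts = 0
    max_attempts = 1000 * n_needed
    while len(picked) < n_needed:
        k = min(4 * (n_needed - len(picked)), max_attempts - attempts)
        if k <= 0:
            raise RuntimeError(
                f"could not place {n_needed} negatives >= {min_dist} bp from TSS "
                f"after {attempts} draws; regions too dense with TSS"
            )
        attempts += k
        offs = rng.integers(0, total, size=k)
        ridx = np.searchsorted(cum, offs, side="right") - 1
        for o, ri in zip(offs, ridx):
            chrom, start, _ = regions[ri]
            pos = int(start + (o - cum[ri]))
            key = (chrom, pos)
            if key in seen:
                continue
            tss = tss_by_chrom.get(chrom)
            if tss is not None and tss.size:
                i = np.searchsorted(tss, pos)
                near = (i > 0 and pos - tss[i - 1] < min_dist) or (
                    i < tss.size and tss[i] - pos < min_dist
                )
                if near:
                    continue
            seen.add(key)
            picked.append(key)
            if len(picked) == n_needed:
                break
    return picked


def extract_features(
    positions: list, labels, tracks: list, meta: dict | None = None
) -> FeatureMatrix:
    """Sample normalized feature tracks at example positions.

    Row *i*, column *j* is the value of ``tracks[j]`` in the step-cell
    containing ``positions[i]`` (no interpolation — tracks are
    piecewise-constant).
    """
    chroms = [c for c, _ in positions]
    poss = [p for _, p in positions]
    cols = {}
    for t in tracks:
        if not t.name:
            raise ValueError("feature tracks must be named")
        try:
            cols[t.name] = t.values_at(chroms, poss)
        except IndexError as exc:
            raise IndexError(f"feature {t.name!r}: {exc}") from None
    return FeatureMatrix(pd.DataFrame(cols), labels, list(positions), meta or {})
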