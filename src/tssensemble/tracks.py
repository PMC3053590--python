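"""Genomic score tracks and point predictions.

The universal currency of the ensemble is the :class:`ScoreTrack`: a
non-negative score for every position (or every ``step``-bp cell) of a
genome.  Promoter predictors that emit discrete, scored point calls are
converted into tracks by trapezoid expansion — full score over a central
plateau around the call, decaying linearly to zero at the window edges —
so that heterogeneous programs become comparable, continuous features.

Coordinates follow the BED convention throughout: 0-based positions,
half-open intervals.  Tracks are unstranded; strand-specific predictors
contribute one track per strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "ScoreTrack",
    "PointPredictionSet",
    "TrapezoidKernel",
    "read_points",
    "write_points",
    "read_track",
    "write_track",
    "trapezoid_expand",
    "normalize_track",
    "average_tracks",
    "decimate_track",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of a genome assembly.

    Parameters
    ----------
    lengths
        Mapping ``chromosome name -> length in bp``.  Names are unique by
        construction; lengths must be positive integers.
    """

    lengths: tuple

    def __init__(self, lengths):
        if hasattr(lengths, "items"):
            items = tuple(lengths.items())
        else:
            items = tuple(tuple(x) for x in lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for n, L in items:
            if int(L) != L or L <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {L}")
        object.__setattr__(self, "lengths", tuple((n, int(L)) for n, L in items))

    @property
    def names(self) -> list:
        return [n for n, _ in self.lengths]

    def length(self, chrom: str) -> int:
        for n, L in self.lengths:
            if n == chrom:
                return L
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(n == chrom for n, _ in self.lengths)

    def n_cells(self, chrom: str, step: int) -> int:
        return -(-self.length(chrom) // step)

    @property
    def total_length(self) -> int:
        return sum(L for _, L in self.lengths)


@dataclass
class ScoreTrack:
    """Per-cell scores over a genome layout.

    ``values[chrom]`` holds one float array per chromosome of length
    ``ceil(length / step)``; cell *i* covers bases ``[i*step, (i+1)*step)``.
    ``norm_bounds`` records the (lo, hi) used by :func:`normalize_track` so
    the identical affine transform can be re-applied genome-wide at
    prediction time.
    """

    layout: GenomeLayout
    step: int
    values: dict
    name: str = ""
    norm_bounds: tuple | None = None

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("step must be >= 1")
        for chrom in self.layout.names:
            if chrom not in self.values:
                raise ValueError(f"missing values for chromosome {chrom!r}")
            n = self.layout.n_cells(chrom, self.step)
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (n,):
                raise ValueError(
                    f"{chrom!r}: expected {n} cells at step {self.step}, got {v.shape}"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom!r}: non-finite scores")
            self.values[chrom] = v

    @classmethod
    def zeros(cls, layout: GenomeLayout, step: int = 1, name: str = "") -> "ScoreTrack":
        vals = {c: np.zeros(layout.n_cells(c, step)) for c in layout.names}
        return cls(layout, step, vals, name=name)

    def value_at(self, chrom: str, pos: int) -> float:
        if pos < 0 or pos >= self.layout.length(chrom):
            raise IndexError(f"position {chrom}:{pos} outside layout")
        return float(self.values[chrom][pos // self.step])

    def values_at(self, chroms, positions) -> np.ndarray:
        """Vectorised step-aware lookup (value of the containing cell)."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=int)
        out = np.empty(len(positions))
        for chrom in np.unique(chroms):
            m = chroms == chrom
            pos = positions[m]
            L = self.layout.length(str(chrom))
            if pos.size and (pos.min() < 0 or pos.max() >= L):
                bad = pos[(pos < 0) | (pos >= L)][0]
                raise IndexError(f"position {chrom}:{bad} outside layout")
            out[m] = self.values[str(chrom)][pos // self.step]
        return out

    def max(self) -> float:
        return max(float(v.max()) if v.size else 0.0 for v in self.values.values())

    def copy(self, **changes) -> "ScoreTrack":
        new_vals = {c: v.copy() for c, v in self.values.items()}
        return replace(self, values=new_vals, **changes)

    def __eq__(self, other):
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.step == other.step
            and all(np.array_equal(self.values[c], other.values[c]) for c in self.layout.names)
        )


@dataclass
class PointPredictionSet:
    """Discrete scored predictions: (chromosome, 0-based position, strand, score).

    Backed by a DataFrame with columns ``chrom, pos, strand, score``.
    Duplicate positions are retained — deduplication is the job of
    clustering (see :func:`tssensemble.diversity.cluster_points`).
    """

    records: pd.DataFrame
    name: str = ""

    COLUMNS = ("chrom", "pos", "strand", "score")

    def __post_init__(self):
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        df["pos"] = df["pos"].astype(int)
        df["score"] = df["score"].astype(float)
        df["strand"] = df["strand"].fillna(".").astype(str)
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, chrom, pos, strand=None, score=None, name=""):
        n = len(pos)
        df = pd.DataFrame(
            {
                "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
                "pos": pos,
                "strand": strand if strand is not None else ["."] * n,
                "score": score if score is not None else [0.0] * n,
            }
        )
        return cls(df, name=name)

    def __len__(self) -> int:
        return len(self.records)

    def sort_canonical(self) -> "PointPredictionSet":
        """Deterministic order: chromosome, position ascending, score descending."""
        df = self.records.sort_values(
            ["chrom", "pos", "score"], ascending=[True, True, False], kind="mergesort"
        ).reset_index(drop=True)
        return PointPredictionSet(df, name=self.name)

    def positions_for(self, chrom: str) -> np.ndarray:
        return self.records.loc[self.records["chrom"] == chrom, "pos"].to_numpy()


@dataclass(frozen=True)
class TrapezoidKernel:
    """Trapezoid point-to-track expansion kernel.

    ``window`` is the total support width in bp, ``plateau`` the central
    full-score width.  The defaults (1000/200) give full score within
    ±100 bp of a call, decaying linearly to zero at ±500 bp.
    """

    window: int = 1000
    plateau: int = 200

    def __post_init__(self):
        if not (0 < self.plateau <= self.window):
            raise ValueError("require 0 < plateau <= window")

    def profile(self, offsets: np.ndarray) -> np.ndarray:
        """Kernel weight at signed bp offsets from the point (peak weight 1)."""
        d = np.abs(np.asarray(offsets, dtype=float))
        half, ph = self.window / 2.0, self.plateau / 2.0
        if half == ph:  # pure box kernel
            return (d <= ph).astype(float)
        w = (half - d) / (half - ph)
        return np.clip(np.where(d <= ph, 1.0, w), 0.0, 1.0)


# ---------------------------------------------------------------------------
# I/O: BED-like points, bedGraph and fixedStep wiggle tracks
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_points(path, layout: GenomeLayout | None = None, name: str = "") -> PointPredictionSet:
    """Read scored point predictions from a BED-like file.

    Accepted per-line layouts (whitespace-separated):
    ``chrom start score`` | ``chrom start end score`` |
    ``chrom start end name score [strand]`` (BED5/BED6).
    Intervals are represented by their 0-based start coordinate.
    Malformed lines raise with the offending line number.
    """
    chroms, poss, strands, scores = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            f = line.split()
            try:
                if len(f) == 3:
                    chrom, pos, score, strand = f[0], int(f[1]), float(f[2]), "."
                elif len(f) == 4:
                    chrom, pos, score, strand = f[0], int(f[1]), float(f[3]), "."
                    int(f[2])
                elif len(f) >= 5:
                    chrom, pos, score = f[0], int(f[1]), float(f[4])
                    int(f[2])
                    strand = f[5] if len(f) >= 6 else "."
                else:
                    raise ValueError("expected at least 3 columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if layout is not None:
                if chrom not in layout:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if not (0 <= pos < layout.length(chrom)):
                    raise ValueError(f"{path}:{lineno}: position {pos} outside {chrom}")
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            scores.append(score)
    return PointPredictionSet.from_arrays(chroms, poss, strands, scores, name=name)


def write_points(points: PointPredictionSet, path) -> None:
    """Write as 6-column BED (1-bp intervals)."""
    with open(path, "w") as fh:
        for i, r in enumerate(points.records.itertuples(index=False)):
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\tp{i}\t{r.score:g}\t{r.strand}\n"
            )


def read_track(path, layout: GenomeLayout, step: int = 1, name: str = "") -> ScoreTrack:
    """Read a score track from bedGraph or fixedStep wiggle text.

    Unspecified positions score 0.  bedGraph intervals are half-open and
    must not overlap; fixedStep blocks use the wiggle convention of
    1-based starts.  For fixedStep input whose declared step matches the
    block alignment, the native resolution is kept; otherwise the track is
    materialised at ``step``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if any(ln.startswith("fixedStep") for ln in lines):
        return _read_fixedstep(lines, layout, name=name, src=path)
    return _read_bedgraph(lines, layout, step, name=name, src=path)


def _read_bedgraph(lines, layout, step, name, src) -> ScoreTrack:
    track = ScoreTrack.zeros(layout, step=step, name=name)
    covered = {c: np.zeros(layout.n_cells(c, step), dtype=bool) for c in layout.names}
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        f = line.split()
        if len(f) < 4:
            raise ValueError(f"{src}:{lineno}: expected 'chrom start end value'")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if chrom not in layout:
            raise ValueError(f"{src}:{lineno}: unknown chromosome {chrom!r}")
        if end <= start:
            raise ValueError(f"{src}:{lineno}: interval end {end} <= start {start}")
        if start < 0 or end > layout.length(chrom):
            raise ValueError(f"{src}:{lineno}: interval beyond end of {chrom}")
        lo, hi = start // step, -(-end // step)
        if covered[chrom][lo:hi].any():
            raise ValueError(f"{src}:{lineno}: overlapping interval on {chrom}")
        covered[chrom][lo:hi] = True
        track.values[chrom][lo:hi] = value
    return track


def _read_fixedstep(lines, layout, name, src) -> ScoreTrack:
    blocks = []  # (chrom, start0, step, values)
    cur = None
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        if line.startswith("fixedStep"):
            kv = dict(tok.split("=", 1) for tok in line.split()[1:])
            chrom = kv["chrom"]
            if chrom not in layout:
                raise ValueError(f"{src}:{lineno}: unknown chromosome {chrom!r}")
            start0 = int(kv["start"]) - 1  # wiggle is 1-based
            bstep = int(kv.get("step", 1))
            cur = (chrom, start0, bstep, [])
            blocks.append(cur)
        else:
            if cur is None:
                raise ValueError(f"{src}:{lineno}: value before fixedStep header")
            cur[3].append(float(line.split()[0]))
    steps = {b[2] for b in blocks} or {1}
    native = steps.pop() if len(steps) == 1 else 1
    aligned = all(b[1] % b[2] == 0 for b in blocks)
    step = native if aligned and not steps else 1
    track = ScoreTrack.zeros(layout, step=step, name=name)
    for chrom, start0, bstep, vals in blocks:
        v = np.asarray(vals)
        end = start0 + bstep * len(vals)
        if end > layout.length(chrom) + (step - 1):
            raise ValueError(f"fixedStep block beyond end of {chrom}")
        if step == bstep:
            lo = start0 // step
            track.values[chrom][lo : lo + len(vals)] = v
        else:
            for i, val in enumerate(vals):
                a = start0 + i * bstep
                track.values[chrom][a // step : -(-(a + bstep) // step)] = val
    return track


def write_track(track: ScoreTrack, path, fmt: str = "fixedStep") -> None:
    """Write a track as fixedStep wiggle (default) or bedGraph.

    fixedStep output round-trips bit-exactly through :func:`read_track`
    at the same step.  bedGraph output run-length-encodes and omits
    zero runs.
    """
    with open(path, "w") as fh:
        if fmt == "fixedStep":
            for chrom in track.layout.names:
                fh.write(f"fixedStep chrom={chrom} start=1 step={track.step} span={track.step}\n")
                fh.write("\n".join(repr(float(x)) for x in track.values[chrom]))
                fh.write("\n")
        elif fmt == "bedGraph":
            for chrom in track.layout.names:
                v = track.values[chrom]
                L = track.layout.length(chrom)
                edges = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate(([0], edges))
                ends = np.concatenate((edges, [len(v)]))
                for s, e in zip(starts, ends):
                    if v[s] != 0.0:
                        fh.write(
                            f"{chrom}\t{s * track.step}\t{min(e * track.step, L)}\t{v[s]:g}\n"
                        )
        else:
            raise ValueError(f"unknown track format {fmt!r}")


# ---------------------------------------------------------------------------
# Track operations
# ---------------------------------------------------------------------------


def trapezoid_expand(
    points: PointPredictionSet,
    kernel: TrapezoidKernel = TrapezoidKernel(),
    layout: GenomeLayout = None,
    step: int = 1,
    name: str = "",
) -> ScoreTrack:
    """Convert discrete predictions to a continuous track.

    Each point of score *s* contributes ``s * kernel.profile(d)`` at signed
    offset *d*; where trapezoids from nearby points overlap the per-base
    maximum is taken, preserving the probability-like score semantics.
    Points near chromosome edges are truncated silently.
    """
    if layout is None:
        raise ValueError("layout is required")
    track = ScoreTrack.zeros(layout, step=step, name=name or points.name)
    half = kernel.window // 2
    for r in points.records.itertuples(index=False):
        if r.chrom not in layout:
            raise KeyError(f"unknown chromosome {r.chrom!r}")
        n = layout.n_cells(r.chrom, step)
        lo = max(0, (r.pos - half) // step)
        hi = min(n, -(-(r.pos + half + 1) // step))
        offsets = np.arange(lo, hi) * step - r.pos
        contrib = r.score * kernel.profile(offsets)
        np.maximum(track.values[r.chrom][lo:hi], contrib, out=track.values[r.chrom][lo:hi])
    return track


def normalize_track(track: ScoreTrack, lo: float | None = None, hi: float | None = None) -> ScoreTrack:
    """Min-max normalize into [0, 1], clipping out-of-range values.

    If ``lo``/``hi`` are omitted they are taken from the track itself;
    passing bounds computed on training regions freezes the transform so
    it can be re-applied genome-wide.  The bounds used are stored on the
    returned track's ``norm_bounds``.
    """
    if lo is None or hi is None:
        gmin = min(float(v.min()) for v in track.values.values())
        gmax = max(float(v.max()) for v in track.values.values())
        lo = gmin if lo is None else lo
        hi = gmax if hi is None else hi
        if hi == lo:  # constant track: map to 0 (all-zero stays all-zero)
            out = track.copy(norm_bounds=(lo, lo + 1.0))
            for c in out.values:
                out.values[c] = np.clip(out.values[c] - lo, 0.0, 1.0)
            return out
    if hi <= lo:
        raise ValueError(f"require hi > lo, got lo={lo}, hi={hi}")
    out = track.copy(norm_bounds=(float(lo), float(hi)))
    for c in out.values:
        out.values[c] = np.clip((out.values[c] - lo) / (hi - lo), 0.0, 1.0)
    return out


def average_tracks(tracks: list, name: str = "") -> ScoreTrack:
    """Per-position arithmetic mean of tracks sharing layout and step.

    Used e.g. to average methylation profiles over the cell lines of a
    category before they enter the feature set.
    """
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout or t.step != first.step:
            raise ValueError("tracks have mismatched layouts or steps")
    out = first.copy(name=name or first.name, norm_bounds=None)
    for c in out.values:
        out.values[c] = np.mean([t.values[c] for t in tracks], axis=0)
    return out


def decimate_track(track: ScoreTrack, step: int) -> ScoreTrack:
    """Reduce resolution by max-pooling to a coarser step.

    Max-pooling preserves peak heights, so thresholded point extraction is
    unchanged for isolated peaks.  ``step`` must be a multiple of the
    track's step.
    """
    if step % track.step != 0:
        raise ValueError(f"step {step} is not a multiple of track step {track.step}")
    factor = step // track.step
    if factor == 1:
        return track.copy()
    vals = {}
    for c, v in track.values.items():
        n_out = -(-len(v) // factor)
        pad = np.full(n_out * factor, -np.inf)
        pad[: len(v)] = v
        vals[c] = pad.reshape(n_out, factor).max(axis=1)
    return ScoreTrack(track.layout, step, vals, name=track.name, norm_bounds=track.norm_bounds)
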