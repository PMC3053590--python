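"""Synthetic genomes with planted TSS and correlated noisy feature tracks.

The generator emulates the data a promoter-prediction ensemble consumes:
a small multi-chromosome genome, a stranded reference TSS annotation, a
set of per-feature score tracks whose signal bumps sit on the planted
TSS, and CAGE-like tag positions scattered around each TSS.

Key realism knobs mirror what makes the real problem hard:

* background noise is positive and exponential-tailed (non-promoter
  score histograms are right-skewed), with a configurable exact pairwise
  correlation between features, implemented by mixing a shared and a
  private exponential component;
* a configurable fraction of "hard" TSS carries no signal in a
  designated subset of features (typically the strongest ones), so no
  single feature sees every promoter — the heterogeneity a two-level
  ensemble exploits;
* per-TSS amplitude jitter makes weak promoters shade into the noise.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .diversity import ReferenceTSS
from .tracks import GenomeLayout, ScoreTrack

__all__ = ["FeatureModel", "FixtureSpec", "Fixture", "generate", "default_features"]


@dataclass(frozen=True)
class FeatureModel:
    """Shape of one synthetic feature track.

    ``amplitude`` is the mean peak height over a planted TSS, ``width``
    the bump's scale in bp (Gaussian sigma, or plateau half-width for the
    trapezoid shape), ``noise_scale`` the mean of the exponential
    background.  ``blind_to_hard`` features see no signal at "hard" TSS.
    """

    name: str
    amplitude: float = 1.0
    width: int = 300
    noise_scale: float = 0.1
    noise_smooth: int = 100
    shape: str = "gaussian"
    blind_to_hard: bool = False

    def __post_init__(self):
        if self.amplitude < 0 or self.noise_scale < 0 or self.width < 1:
            raise ValueError("amplitude/noise >= 0 and width >= 1 required")
        if self.noise_smooth < 1:
            raise ValueError("noise_smooth must be >= 1 bp")
        if self.shape not in ("gaussian", "trapezoid"):
            raise ValueError(f"unknown bump shape {self.shape!r}")


def default_features() -> list:
    """Seven features with graded signal-to-noise.

    The five strongest are blind to "hard" TSS, which only the two weak,
    noisy features see — so the reduced (top-5) model is clean but
    incomplete while the full model covers everything: the planted
    analogue of the full/reduced crossover the punting rule exploits.
    """
    return [
        FeatureModel("feat_strong_a", amplitude=1.00, width=250, noise_scale=0.10, blind_to_hard=True),
        FeatureModel("feat_strong_b", amplitude=0.95, width=250, noise_scale=0.12, blind_to_hard=True),
        FeatureModel("feat_melt", amplitude=0.85, width=400, noise_scale=0.16, shape="trapezoid", blind_to_hard=True),
        FeatureModel("feat_mid_a", amplitude=0.75, width=300, noise_scale=0.20, blind_to_hard=True),
        FeatureModel("feat_mid_b", amplitude=0.65, width=300, noise_scale=0.24, blind_to_hard=True),
        FeatureModel("feat_weak_a", amplitude=0.43, width=500, noise_scale=0.325, noise_smooth=30),
        FeatureModel("feat_weak_b", amplitude=0.42, width=600, noise_scale=0.330, noise_smooth=30),
    ]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic genome.

    Defaults plant 519 TSS (the size of the real training annotation)
    with >= 2 kb spacing on a ~2 Mbp toy genome of four chromosomes, with
    30% hard TSS invisible to the two strongest features, background
    correlation 0.3, and 3 CAGE-like tags within ±50 bp of each TSS.
    """

    n_chromosomes: int = 4
    chromosome_length: int = 500_000
    n_tss: int = 519
    min_spacing: int = 2000
    features: tuple = field(default_factory=lambda: tuple(default_features()))
    correlation: float = 0.3
    hard_fraction: float = 0.3
    amplitude_jitter: float = 0.25
    tags_per_tss: int = 3
    tag_jitter: int = 50
    seed: int = 42

    def __post_init__(self):
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must lie in [0, 1)")
        if not (0 <= self.hard_fraction <= 1):
            raise ValueError("hard_fraction must lie in [0, 1]")
        per_chrom = -(-self.n_tss // self.n_chromosomes)
        if per_chrom * self.min_spacing >= self.chromosome_length:
            raise ValueError("infeasible TSS spacing for chromosome length")


@dataclass
class Fixture:
    """A generated toy dataset: layout, truth, feature tracks, tags."""

    layout: GenomeLayout
    tss: ReferenceTSS
    tracks: dict
    tags: ReferenceTSS
    hard: np.ndarray  # boolean per TSS row

    @property
    def track_list(self) -> list:
        return list(self.tracks.values())


def _place_tss(rng, length: int, n: int, spacing: int) -> np.ndarray:
    """n sorted positions with pairwise gaps >= spacing, uniform otherwise."""
    slack = length - n * spacing
    u = np.sort(rng.integers(0, slack, size=n))
    return u + np.arange(n) * spacing + spacing // 2


def _bump(shape: str, width: int) -> np.ndarray:
    if shape == "gaussian":
        ext = 4 * width
        d = np.arange(-ext, ext + 1, dtype=float)
        return np.exp(-0.5 * (d / width) ** 2)
    # trapezoid: full score over ±width, linear to zero at ±3*width
    ext = 3 * width
    d = np.abs(np.arange(-ext, ext + 1, dtype=float))
    return np.clip((ext - d) / (ext - width), 0.0, 1.0).clip(max=1.0)


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the fixture described by ``spec`` (bit-identical per seed)."""
    rng = np.random.default_rng(spec.seed)
    names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    layout = GenomeLayout({n: spec.chromosome_length for n in names})

    # distribute TSS over chromosomes as evenly as possible
    base, extra = divmod(spec.n_tss, spec.n_chromosomes)
    counts = [base + (1 if i < extra else 0) for i in range(spec.n_chromosomes)]
    rows = []
    for chrom, k in zip(names, counts):
        for p in _place_tss(rng, spec.chromosome_length, k, spec.min_spacing):
            rows.append((chrom, int(p), "+" if rng.random() < 0.5 else "-"))
    tss = ReferenceTSS(pd.DataFrame(rows, columns=["chrom", "pos", "strand"]))
    n_tss = len(tss)

    hard = np.zeros(n_tss, dtype=bool)
    n_hard = int(round(spec.hard_fraction * n_tss))
    hard[rng.choice(n_tss, size=n_hard, replace=False)] = True

    # per-TSS amplitude jitter shared across features (weak promoters are
    # weak everywhere, mimicking genuinely low-signal TSS)
    jitter = np.exp(rng.normal(0.0, spec.amplitude_jitter, size=n_tss))

    # correlated exponential background: X_i = w*S + (1-w)*E_i has exact
    # pairwise correlation w^2 / (w^2 + (1-w)^2)
    rho = spec.correlation
    w = np.sqrt(rho) / (np.sqrt(rho) + np.sqrt(1 - rho)) if rho > 0 else 0.0

    tracks = {}
    profiles = {f.name: _bump(f.shape, f.width) for f in spec.features}
    shared = {c: rng.exponential(1.0, size=spec.chromosome_length) for c in names}
    for f in spec.features:
        vals = {}
        for c in names:
            own = rng.exponential(1.0, size=spec.chromosome_length)
            raw = f.noise_scale * (w * shared[c] + (1 - w) * own)
            # smooth to a realistic correlation length; linear filtering
            # applied identically per feature preserves the pairwise
            # correlation and keeps the noise positive and right-skewed
            vals[c] = uniform_filter1d(raw, size=f.noise_smooth, mode="nearest")
        prof = profiles[f.name]
        ext = len(prof) // 2
        for i, r in enumerate(tss.records.itertuples(index=False)):
            if f.blind_to_hard and hard[i]:
                continue
            amp = f.amplitude * jitter[i]
            lo = max(0, r.pos - ext)
            hi = min(spec.chromosome_length, r.pos + ext + 1)
            seg = prof[lo - (r.pos - ext) : len(prof) - ((r.pos + ext + 1) - hi)]
            np.maximum(vals[r.chrom][lo:hi], amp * seg, out=vals[r.chrom][lo:hi])
        tracks[f.name] = ScoreTrack(layout, 1, vals, name=f.name)

    tag_rows = []
    for r in tss.records.itertuples(index=False):
        offs = rng.integers(-spec.tag_jitter, spec.tag_jitter + 1, size=spec.tags_per_tss)
        for o in offs:
            p = int(np.clip(r.pos + o, 0, spec.chromosome_length - 1))
            tag_rows.append((r.chrom, p, r.strand))
    tags = ReferenceTSS(pd.DataFrame(tag_rows, columns=["chrom", "pos", "strand"]))

    return Fixture(layout, tss, tracks, tags, hard)
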