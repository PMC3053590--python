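"""End-to-end workflow on a synthetic fixture.

Wires every stage together the way a real study would: normalize the
feature tracks on the training chromosomes, build the labelled training
matrix (all TSS in the training regions as positives, 5x uniform
negatives at >= 1 kb from any TSS), rank features and fit the two-level
ensemble, learn the punting threshold on a held-out chromosome, then
score everything on a final evaluation chromosome.  Used by the tests,
the acceptance script and the README worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import PuntingEnsemble, PuntingEnsembleResults, SvmConfig
from .evaluation import EvaluationCurve, background_positions, sens_spec_curve
from .synthetic import Fixture, FixtureSpec, generate
from .tracks import ScoreTrack, normalize_track
from .trainset import extract_features, sample_negatives, sample_positives
from .diversity import ReferenceTSS

__all__ = ["PipelineResult", "run_fixture_pipeline", "subset_ref"]


def subset_ref(ref: ReferenceTSS, chroms) -> ReferenceTSS:
    sub = ref.records[ref.records["chrom"].isin(list(chroms))]
    return ReferenceTSS(sub.reset_index(drop=True))


@dataclass
class PipelineResult:
    """Everything the fixture run produces, for inspection and testing."""

    fixture: Fixture
    results: PuntingEnsembleResults
    theta: float
    tracks_norm: dict
    reduced_track: ScoreTrack
    full_track: ScoreTrack
    combined_track: ScoreTrack
    eval_ref: ReferenceTSS
    eval_negatives: list
    curves: dict  # name -> EvaluationCurve on the evaluation chromosome
    auc: dict  # name -> AUC on the evaluation chromosome

    def summary(self) -> str:
        lines = [self.results.summary(), "", "evaluation-chromosome AUC"]
        for name, a in sorted(self.auc.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {name:<28}{a:.3f}")
        return "\n".join(lines)


def run_fixture_pipeline(
    spec: FixtureSpec = FixtureSpec(),
    config: SvmConfig = SvmConfig(),
    k_reduced: int = 5,
    step: int = 5,
    tol: int = 500,
    eval_step: int = 5,
) -> PipelineResult:
    """Run the full two-level ensemble study on a synthetic fixture.

    Chromosome split: all but the last two train the models, the
    second-to-last learns theta, the last is the evaluation region.
    """
    fx = generate(spec)
    names = fx.layout.names
    if len(names) < 3:
        raise ValueError("pipeline needs >= 3 chromosomes (train/theta/eval)")
    train_chroms, theta_chrom, eval_chrom = names[:-2], names[-2], names[-1]
    train_regions = [(c, 0, fx.layout.length(c)) for c in train_chroms]

    # freeze normalization on the training regions, apply genome-wide
    tracks_norm = {}
    for name, t in fx.tracks.items():
        lo = min(float(t.values[c].min()) for c in train_chroms)
        hi = max(float(t.values[c].max()) for c in train_chroms)
        tracks_norm[name] = normalize_track(t, lo, hi)

    positives = sample_positives(fx.tss, train_regions)
    negatives = sample_negatives(fx.tss, train_regions, ratio=5, min_dist=1000, seed=spec.seed)
    positions = positives + negatives
    labels = np.array([True] * len(positives) + [False] * len(negatives))
    matrix = extract_features(positions, labels, list(tracks_norm.values()))

    results = PuntingEnsemble(matrix, k_reduced=k_reduced, full_config=config).fit()

    theta_ref = subset_ref(fx.tss, [theta_chrom])
    theta_layout_neg = background_positions(fx.layout, fx.tss, min_dist=1000, spacing=997,
                                            seed=spec.seed)
    theta_neg = [(c, p) for c, p in theta_layout_neg if c == theta_chrom]
    red_t, full_t = results.predict_tracks(list(tracks_norm.values()), step=step)
    results.learn_theta(
        _restrict(red_t, theta_chrom), _restrict(full_t, theta_chrom), theta_ref,
        tol=tol, negatives=theta_neg,
    )
    combined = results.combine(red_t, full_t)

    eval_ref = subset_ref(fx.tss, [eval_chrom])
    eval_neg = [(c, p) for c, p in theta_layout_neg if c == eval_chrom]
    curves, auc = {}, {}
    eval_tracks = {"reduced": red_t, "full": full_t, "combined": combined}
    eval_tracks.update({name: tracks_norm[name] for name in tracks_norm})
    for name, t in eval_tracks.items():
        curves[name] = sens_spec_curve(t, eval_ref, tol, eval_neg)
        auc[name] = curves[name].auc()

    return PipelineResult(
        fixture=fx,
        results=results,
        theta=results.theta,
        tracks_norm=tracks_norm,
        reduced_track=red_t,
        full_track=full_t,
        combined_track=combined,
        eval_ref=eval_ref,
        eval_negatives=eval_neg,
        curves=curves,
        auc=auc,
    )


def _restrict(track: ScoreTrack, chrom: str) -> ScoreTrack:
    from .tracks import GenomeLayout

    layout = GenomeLayout({chrom: track.layout.length(chrom)})
    return ScoreTrack(layout, track.step, {chrom: track.values[chrom].copy()}, name=track.name)
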