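# tssensemble

Genome-wide prediction of transcription start sites (TSS) by combining
heterogeneous promoter predictors into a single probability score track.

Computational promoter predictors disagree substantially — different
programs use different features (sequence k-mers, DNA structure, melting
temperature, methylation, conservation) and miss different promoters,
especially those outside CpG islands. That disagreement is exploitable:
`tssensemble` converts each predictor's output into a comparable
per-base score track, quantifies the diversity between prediction sets,
and trains a **two-level ensemble** that combines them.

## The method

Every feature becomes a `ScoreTrack` (non-negative score per base, BED
coordinate conventions). Discrete point predictions are expanded with a
**trapezoid kernel**: full score over a central plateau (default 200 bp),
decaying linearly to zero at the edges of a window (default 1000 bp).
Tracks are min-max normalized to [0, 1] with bounds frozen on the
training regions.

Training examples are annotated TSS positions (positives) plus five
times as many uniform random positions at least 1000 bp from any TSS
(negatives). Two soft-margin RBF-kernel classifiers with probability
outputs and inverse-class-frequency weights are fitted to this matrix:

* a **full model** over all feature tracks, and
* a **reduced model** over the top-*k* (default 5) features ranked by
  information gain, `IG(X) = H(Y) − Σ_b p(b) H(Y | b)`, with each feature
  discretized by Fayyad–Irani MDL supervised binning (gains in bits).

The reduced model is more accurate at high confidence, the full model at
low confidence, so the two are **"punted"** together: wherever the
reduced probability reaches a threshold θ its score is kept; everywhere
else the full model's score is substituted, rescaled by θ/M (M = the
maximum full score over the replaced positions) so substituted scores
top out at θ. θ is learned on held-out data as the reduced-model
probability at the point where the two models' sensitivity–specificity
curves cross.

The package also provides tolerance-aware ∩/∪ overlap between
prediction sets, TP/FP stratification against a reference TSS
annotation, threshold + greedy-cluster point calling with strand-aware
asymmetric matching, sensitivity–specificity curves with AUC, and
distance-/bin-based protocol scores aggregated by harmonic mean.

## Worked example

The bundled synthetic-fixture generator plants 519 TSS on a ~2 Mbp toy
genome with seven noisy, correlated feature tracks; 30% of TSS are
"hard" — invisible to the five strongest features — so no single feature
sees every promoter:

```python
from tssensemble import FixtureSpec, run_fixture_pipeline

res = run_fixture_pipeline(FixtureSpec(seed=42))
print(res.summary())
```

```
Two-level punting ensemble
============================================
examples: 1560  (promoters: 260, non-promoters: 1300)
punting threshold theta: 0.763

feature                     info gain (bits)  reduced
feat_strong_a                          0.368  *
feat_strong_b                          0.368  *
feat_melt                              0.368  *
feat_mid_a                             0.368  *
feat_mid_b                             0.365  *
feat_weak_a                            0.331
feat_weak_b                            0.287
full model: C=8, gamma=0.5, 7 features
reduced model: C=8, gamma=0.5, 5 features

evaluation-chromosome AUC
  combined                    0.915
  full                        0.915
  feat_strong_a               0.868
  feat_mid_b                  0.863
  feat_mid_a                  0.851
  feat_strong_b               0.845
  reduced                     0.822
  feat_melt                   0.762
  feat_weak_a                 0.695
  feat_weak_b                 0.639
```

The five clean-but-incomplete features rank highest by information gain
and form the reduced set; the combined track (AUC 0.915) beats the best
single feature (0.868) because the full model recovers the hard TSS that
the strong features cannot see. θ = 0.763 is the learned crossover of
the two models' sensitivity–specificity curves on the held-out
chromosome.

A `tssensemble` console script exposes the track, diversity, ranking,
point-calling, evaluation and fixture operations (`tssensemble --help`).

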