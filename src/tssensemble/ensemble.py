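"""Two-level promoter-activity classifier with "punting" combination.

Two soft-margin RBF-kernel classifiers with probability outputs are
trained on the same labelled examples: a *full* model over every feature
track and a *reduced* model over the top-k features by information gain.
The reduced model is more accurate at high confidence, the full model at
low confidence, so the two are combined in an either/or manner: wherever
the reduced model's probability reaches a threshold theta its prediction
is kept; everywhere else the full model's prediction is substituted,
rescaled so the substituted scores never exceed theta.  Theta is learned
on held-out data as the reduced-model probability at the point where the
two models' sensitivity-specificity curves cross.

The module follows the statsmodels convention: :class:`PuntingEnsemble`
is built from a :class:`~tssensemble.trainset.FeatureMatrix`, and
``fit()`` returns a :class:`PuntingEnsembleResults` carrying the fitted
classifiers, the feature ranking, theta and prediction methods.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import EvaluationCurve, sens_spec_curve
from .ranking import FeatureRanking, rank_features, select_top
from .tracks import ScoreTrack
from .trainset import FeatureMatrix

__all__ = [
    "SvmConfig",
    "FittedModel",
    "train_model",
    "grid_search",
    "predict_track",
    "learn_theta",
    "punt_combine",
    "PuntingEnsemble",
    "PuntingEnsembleResults",
]

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SvmConfig:
    """RBF-kernel classifier hyperparameters.

    ``class_weight=None`` means inverse-class-frequency weighting (so a
    1:5 promoter:non-promoter imbalance weights errors 5:1).  ``seed``
    fixes the probability-calibration fold shuffling, making training
    deterministic.
    """

    C: float = 8.0
    gamma: float = 0.5
    class_weight: dict | None = None
    probability: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


@dataclass
class FittedModel:
    """A fitted probabilistic classifier bound to named feature tracks."""

    clf: SVC
    feature_names: list
    config: SvmConfig

    def predict_proba(self, X) -> np.ndarray:
        """P(promoter) for rows of X (DataFrame with named columns, or array)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        col = int(np.flatnonzero(self.clf.classes_ == 1)[0])
        return self.clf.predict_proba(X)[:, col]


def train_model(m: FeatureMatrix, cfg: SvmConfig = SvmConfig()) -> FittedModel:
    """Fit one RBF-kernel probabilistic classifier on a feature matrix."""
    y = m.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(
        C=cfg.C,
        gamma=cfg.gamma,
        kernel="rbf",
        class_weight=cfg.class_weight if cfg.class_weight is not None else "balanced",
        probability=cfg.probability,
        random_state=cfg.seed,
    )
    clf.fit(m.X, y)
    return FittedModel(clf, m.feature_names, cfg)


def grid_search(
    m: FeatureMatrix,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> SvmConfig:
    """Pick (C, gamma) maximising mean cross-validated AUC.

    Exhaustive search over the Cartesian product of the grids with
    stratified k-fold CV; AUC is computed from decision values, which
    avoids refitting the probability calibration at every grid point.
    Ties go to the first (smallest C, then smallest gamma) grid point.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = m.X, m.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for C in C_grid:
        for gamma in gamma_grid:
            aucs = []
            for tr, te in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced")
                clf.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, C, gamma)
    return SvmConfig(C=best[1], gamma=best[2], seed=seed)


def predict_track(model: FittedModel, tracks: list, step: int = 5, chunk: int = 65536) -> ScoreTrack:
    """Genome-wide P(promoter) track at the given step.

    ``tracks`` must include a normalized track for every feature of the
    model; prediction samples each track at the start of every
    ``step``-bp cell and runs the classifier in chunks.
    """
    by_name = {t.name: t for t in tracks}
    missing = [f for f in model.feature_names if f not in by_name]
    if missing:
        raise KeyError(f"missing feature track(s): {', '.join(missing)}")
    layout = next(iter(by_name.values())).layout
    out = ScoreTrack.zeros(layout, step=step, name="ensemble")
    for chrom in layout.names:
        n = layout.n_cells(chrom, step)
        for lo in range(0, n, chunk):
            hi = min(n, lo + chunk)
            pos = np.arange(lo, hi, dtype=np.int64) * step
            X = np.column_stack(
                [by_name[f].values[chrom][pos // by_name[f].step] for f in model.feature_names]
            )
            out.values[chrom][lo:hi] = model.predict_proba(X)
    return out


def learn_theta(
    reduced: ScoreTrack,
    full: ScoreTrack,
    ref,
    tol: int = 500,
    negatives: list = None,
    grid_points: int = 1000,
) -> float:
    """Find the punting threshold from held-out sensitivity-specificity curves.

    Both probability tracks are evaluated against the reference TSS of
    the held-out region; sensitivities are interpolated onto a common
    specificity grid, and, scanning from high specificity downward, the
    first point where the reduced model stops dominating is the
    crossover.  Theta is the reduced-model probability threshold whose
    specificity equals that crossover.  If the curves never cross the
    result is 0 (reduced dominates everywhere) or 1 (full dominates).
    """
    from .evaluation import background_positions

    if negatives is None:
        negatives = background_positions(reduced.layout, ref)
    curve_r = sens_spec_curve(reduced, ref, tol, negatives)
    curve_f = sens_spec_curve(full, ref, tol, negatives)
    grid = np.linspace(0.0, 1.0, grid_points)
    sens_r = curve_r.sensitivity_at_specificity(grid)
    sens_f = curve_f.sensitivity_at_specificity(grid)
    diff = sens_r - sens_f
    if np.all(diff >= -1e-12):
        return 0.0
    if np.all(diff <= 1e-12):
        return 1.0
    # scan from the high-specificity end for the first strict loss
    losing = np.flatnonzero(diff < -1e-12)
    cross_spec = grid[losing[-1]]  # highest specificity at which reduced loses
    theta = curve_r.threshold_at_specificity(cross_spec)
    return float(min(max(theta, 0.0), 1.0))


def punt_combine(reduced: ScoreTrack, full: ScoreTrack, theta: float) -> ScoreTrack:
    """Either/or combination of the two probability tracks.

    Positions where the reduced score reaches ``theta`` keep it; all
    other positions take the full-model score rescaled by ``theta / M``,
    where M is the genome-wide maximum full score over the replaced
    positions — the substituted scores thus top out at exactly theta.
    Every combined value above theta therefore originates from the
    reduced model, and the full model's ranking among replaced positions
    is preserved.  (An all-zero replaced region is left at zero.)
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie strictly between 0 and 1")
    if reduced.layout != full.layout or reduced.step != full.step:
        raise ValueError("tracks have mismatched layouts or steps")
    replaced_max = 0.0
    for c in reduced.layout.names:
        m = reduced.values[c] < theta
        if m.any():
            replaced_max = max(replaced_max, float(full.values[c][m].max()))
    scale = theta / replaced_max if replaced_max > 0 else 1.0
    out = reduced.copy(name="combined", norm_bounds=None)
    for c in reduced.layout.names:
        m = reduced.values[c] < theta
        out.values[c][m] = full.values[c][m] * scale
    return out


class PuntingEnsemble:
    """Two-level ensemble model over a labelled feature matrix.

    Parameters
    ----------
    matrix
        Normalized examples x features table with promoter labels.
    k_reduced
        Size of the reduced feature set (top-k by information gain).
    full_config, reduced_config
        Hyperparameters of the two classifiers (shared default).
    theta
        Initial punting threshold; typically re-learned on held-out data
        via :meth:`PuntingEnsembleResults.learn_theta`.
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        k_reduced: int = 5,
        full_config: SvmConfig = SvmConfig(),
        reduced_config: SvmConfig | None = None,
        theta: float = 0.94,
    ):
        if not (1 <= k_reduced <= len(matrix.feature_names)):
            raise ValueError("k_reduced out of range")
        self.matrix = matrix
        self.k_reduced = k_reduced
        self.full_config = full_config
        self.reduced_config = reduced_config or full_config
        self.theta = theta

    @classmethod
    def from_tracks(cls, positions, labels, tracks, **kwargs) -> "PuntingEnsemble":
        from .trainset import extract_features

        return cls(extract_features(positions, labels, tracks), **kwargs)

    def fit(self, do_grid_search: bool = False, folds: int = 5, cv_auc_folds: int = 0):
        """Rank features, train both classifiers, return a results object.

        ``do_grid_search`` tunes (C, gamma) per model by cross-validated
        AUC first; ``cv_auc_folds > 0`` additionally records out-of-fold
        AUC diagnostics for the summary table.
        """
        ranking = rank_features(self.matrix)
        reduced_names = select_top(ranking, self.k_reduced)
        reduced_matrix = self.matrix.subset(reduced_names)
        full_cfg, reduced_cfg = self.full_config, self.reduced_config
        if do_grid_search:
            full_cfg = grid_search(self.matrix, folds=folds, seed=full_cfg.seed)
            reduced_cfg = grid_search(reduced_matrix, folds=folds, seed=reduced_cfg.seed)
        full_model = train_model(self.matrix, full_cfg)
        reduced_model = train_model(reduced_matrix, reduced_cfg)
        cv_auc = {}
        if cv_auc_folds >= 2:
            for label, mat, cfg in (
                ("full", self.matrix, full_cfg),
                ("reduced", reduced_matrix, reduced_cfg),
            ):
                skf = StratifiedKFold(cv_auc_folds, shuffle=True, random_state=cfg.seed)
                scores = np.zeros(len(mat))
                for tr, te in skf.split(mat.X, mat.y):
                    clf = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf", class_weight="balanced")
                    clf.fit(mat.X[tr], mat.y[tr])
                    scores[te] = clf.decision_function(mat.X[te])
                cv_auc[label] = float(roc_auc_score(mat.y, scores))
        return PuntingEnsembleResults(
            model=self,
            ranking=ranking,
            reduced_features=reduced_names,
            full_model=full_model,
            reduced_model=reduced_model,
            theta=self.theta,
            cv_auc=cv_auc,
        )


@dataclass
class PuntingEnsembleResults:
    """Fitted two-level ensemble: classifiers, ranking and threshold."""

    model: PuntingEnsemble
    ranking: FeatureRanking
    reduced_features: list
    full_model: FittedModel
    reduced_model: FittedModel
    theta: float
    cv_auc: dict = field(default_factory=dict)

    def predict_matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-row reduced/full/combined probabilities for a feature table."""
        p_red = self.reduced_model.predict_proba(data)
        p_full = self.full_model.predict_proba(data)
        keep = p_red >= self.theta
        replaced = p_full[~keep]
        m = replaced.max() if replaced.size else 0.0
        scale = self.theta / m if m > self.theta else 1.0
        combined = np.where(keep, p_red, p_full * scale)
        return pd.DataFrame({"reduced": p_red, "full": p_full, "combined": combined})

    def predict_tracks(self, tracks: list, step: int = 5) -> tuple:
        """Genome-wide (reduced, full) probability tracks."""
        red = predict_track(self.reduced_model, tracks, step=step)
        red.name = "reduced"
        full = predict_track(self.full_model, tracks, step=step)
        full.name = "full"
        return red, full

    def learn_theta(self, reduced: ScoreTrack, full: ScoreTrack, ref, tol: int = 500,
                    negatives: list = None) -> float:
        """Learn and store the punting threshold on a held-out region."""
        self.theta = learn_theta(reduced, full, ref, tol=tol, negatives=negatives)
        return self.theta

    def combine(self, reduced: ScoreTrack, full: ScoreTrack) -> ScoreTrack:
        """Punting combination at the stored theta (edge thetas short-circuit)."""
        if self.theta <= 0.0:
            return reduced.copy(name="combined")
        if self.theta >= 1.0:
            return full.copy(name="combined")
        return punt_combine(reduced, full, self.theta)

    def summary(self) -> str:
        lines = [
            "Two-level punting ensemble",
            "=" * 44,
            f"examples: {len(self.model.matrix)}  "
            f"(promoters: {int(self.model.matrix.labels.sum())}, "
            f"non-promoters: {int((~self.model.matrix.labels).sum())})",
            f"punting threshold theta: {self.theta:.3f}",
            "",
            f"{'feature':<28}{'info gain (bits)':>16}  reduced",
        ]
        for name, gain in self.ranking.entries:
            mark = "*" if name in self.reduced_features else ""
            lines.append(f"{name:<28}{gain:>16.3f}  {mark}")
        for label, model in (("full", self.full_model), ("reduced", self.reduced_model)):
            cfg = model.config
            auc = f", CV AUC {self.cv_auc[label]:.3f}" if label in self.cv_auc else ""
            lines.append(f"{label} model: C={cfg.C:g}, gamma={cfg.gamma:g}"
                         f", {len(model.feature_names)} features{auc}")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PuntingEnsembleResults":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a saved ensemble")
        return obj
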