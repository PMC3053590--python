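import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from tssensemble import (
    GenomeLayout,
    PuntingEnsemble,
    ReferenceTSS,
    ScoreTrack,
    SvmConfig,
    grid_search,
    learn_theta,
    predict_track,
    punt_combine,
    train_model,
)
from tssensemble.trainset import FeatureMatrix


def toy_matrix(n=100, seed=0, separation=2.0):
    """Two Gaussian blobs in 2 features, linearly separable at high separation."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2 == 0
    X = rng.normal(0, 0.3, size=(n, 2)) + separation * y[:, None]
    X = (X - X.min()) / (X.max() - X.min())
    return FeatureMatrix(
        pd.DataFrame(X, columns=["fa", "fb"]), y, [("chr1", i) for i in range(n)]
    )


def make_track(layout, arrays, step=1, name="t"):
    return ScoreTrack(layout, step, arrays, name=name)


class TestTrainModel:
    def test_separable_toy_perfect_training_fit(self):
        m = toy_matrix(separation=3.0)
        model = train_model(m, SvmConfig(C=10, gamma=1.0))
        p = model.predict_proba(m.data)
        assert np.all((p > 0.5) == m.labels)

    def test_single_class_error(self):
        m = toy_matrix()
        m2 = FeatureMatrix(m.data, np.ones(len(m), dtype=bool), m.positions)
        with pytest.raises(ValueError, match="single class"):
            train_model(m2)

    def test_permuted_labels_near_chance_auc(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(n=200, separation=3.0)
        y_perm = rng.permutation(m.labels)
        m2 = FeatureMatrix(m.data, y_perm, m.positions)
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        scores = np.zeros(len(m2))
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(m2.X, m2.y):
            clf = SVC(C=8, gamma=0.5, class_weight="balanced").fit(m2.X[tr], m2.y[tr])
            scores[te] = clf.decision_function(m2.X[te])
        assert roc_auc_score(m2.y, scores) == pytest.approx(0.5, abs=0.15)

    def test_row_duplication_leaves_decision_unchanged(self):
        m = toy_matrix(n=80, separation=2.0)
        m_dup = FeatureMatrix(
            pd.concat([m.data, m.data], ignore_index=True),
            np.concatenate([m.labels, m.labels]),
            [("chr1", i) for i in range(2 * len(m))],
        )
        p1 = train_model(m, SvmConfig(seed=0)).predict_proba(m.data)
        p2 = train_model(m_dup, SvmConfig(seed=0)).predict_proba(m.data)
        assert np.allclose(p1 > 0.5, p2 > 0.5)
        assert np.abs(p1 - p2).mean() < 0.1

    def test_deterministic_for_fixed_seed(self):
        m = toy_matrix()
        p1 = train_model(m, SvmConfig(seed=3)).predict_proba(m.data)
        p2 = train_model(m, SvmConfig(seed=3)).predict_proba(m.data)
        assert np.array_equal(p1, p2)


class TestGridSearch:
    def test_singleton_grid_returned(self):
        m = toy_matrix(n=60)
        cfg = grid_search(m, C_grid=[2.0], gamma_grid=[0.25], folds=3)
        assert (cfg.C, cfg.gamma) == (2.0, 0.25)

    def test_result_in_grid_and_argmax(self):
        m = toy_matrix(n=80, separation=1.0, seed=2)
        Cs, gs = [0.5, 8.0], [0.1, 2.0]
        cfg = grid_search(m, C_grid=Cs, gamma_grid=gs, folds=3, seed=0)
        assert cfg.C in Cs and cfg.gamma in gs

    def test_folds_validation(self):
        with pytest.raises(ValueError):
            grid_search(toy_matrix(), folds=1)


class TestPredictTrack:
    def test_output_shape_and_determinism(self, layout):
        m = toy_matrix()
        model = train_model(m, SvmConfig(seed=0))
        tracks = [ScoreTrack.zeros(layout, name="fa"), ScoreTrack.zeros(layout, name="fb")]
        tracks[0].values["chr1"][:500] = 0.9
        tracks[1].values["chr1"][:500] = 0.9
        out = predict_track(model, tracks, step=5)
        assert len(out.values["chr1"]) == 2000
        assert np.all((out.values["chr1"] >= 0) & (out.values["chr1"] <= 1))
        # identical feature vectors -> identical scores
        assert out.values["chr1"][0] == out.values["chr1"][10]
        out2 = predict_track(model, tracks, step=5)
        assert out == out2

    def test_missing_feature_track_named(self, layout):
        m = toy_matrix()
        model = train_model(m)
        with pytest.raises(KeyError, match="fb"):
            predict_track(model, [ScoreTrack.zeros(layout, name="fa")])


def _theta_fixture(seed=0):
    """Planted crossover: reduced model wins above probability ~0.9.

    Easy TSS score U(0.92, 1) in the reduced track and hard TSS near
    background, while the full track scores every TSS U(0.88, 0.92);
    negatives score U(0, 1) in both.  The reduced curve therefore
    dominates exactly for thresholds above 0.9.
    """
    rng = np.random.default_rng(seed)
    n_tss, spacing = 150, 2000
    L = spacing * (2 * n_tss + 2)
    lay = GenomeLayout({"chr1": L})
    tss_pos = spacing * (2 * np.arange(n_tss) + 1)
    mid = spacing * 2 * np.arange(1, n_tss + 1)  # halfway between TSS
    neg_pos = np.concatenate((mid, mid - 1000))  # all >= 1 kb from any TSS

    red = ScoreTrack.zeros(lay, name="red")
    full = ScoreTrack.zeros(lay, name="full")
    easy = np.arange(n_tss) % 2 == 0
    red.values["chr1"][tss_pos[easy]] = rng.uniform(0.92, 1.0, easy.sum())
    red.values["chr1"][tss_pos[~easy]] = rng.uniform(0.0, 0.3, (~easy).sum())
    full.values["chr1"][tss_pos] = rng.uniform(0.88, 0.92, n_tss)
    red.values["chr1"][neg_pos] = rng.uniform(0, 1, len(neg_pos))
    full.values["chr1"][neg_pos] = rng.uniform(0, 1, len(neg_pos))

    ref = ReferenceTSS.from_arrays(["chr1"] * n_tss, tss_pos, ["+"] * n_tss)
    negatives = [("chr1", int(p)) for p in neg_pos]
    return red, full, ref, negatives


class TestLearnTheta:
    def test_reduced_dominates_everywhere_gives_zero(self):
        red, full, ref, neg = _theta_fixture()
        # make the reduced track a strictly better scorer everywhere
        boosted = red.copy()
        boosted.values["chr1"][ref.records["pos"]] = 1.0
        assert learn_theta(boosted, full, ref, tol=500, negatives=neg) == 0.0

    def test_full_dominates_everywhere_gives_one(self):
        red, full, ref, neg = _theta_fixture()
        boosted = full.copy()
        boosted.values["chr1"][ref.records["pos"]] = 1.0
        assert learn_theta(red, boosted, ref, tol=500, negatives=neg) == 1.0

    def test_planted_crossover_recovered(self):
        red, full, ref, neg = _theta_fixture()
        theta = learn_theta(red, full, ref, tol=500, negatives=neg)
        assert theta == pytest.approx(0.9, abs=0.05)


class TestPuntCombine:
    def layout(self):
        return GenomeLayout({"c": 4})

    def track(self, vals):
        lay = self.layout()
        return ScoreTrack(lay, 1, {"c": np.array(vals, dtype=float)})

    def test_worked_scaling_example(self):
        reduced = self.track([0.95, 0.5, 0.2, 0.99])
        full = self.track([0.1, 0.8, 0.5, 0.9])
        out = punt_combine(reduced, full, 0.94)
        assert out.values["c"][0] == 0.95  # kept branch
        assert out.values["c"][1] == pytest.approx(0.94 * 0.8 / 0.8)
        assert out.values["c"][2] == pytest.approx(0.5 * 0.94 / 0.8)
        assert out.values["c"][3] == 0.99

    def test_identity_when_reduced_above_theta(self):
        reduced = self.track([0.95, 0.96, 0.97, 0.99])
        full = self.track([0.1, 0.2, 0.3, 0.4])
        out = punt_combine(reduced, full, 0.94)
        assert out == reduced

    def test_substituted_scores_top_out_at_theta(self):
        reduced = self.track([0.1, 0.2, 0.3, 0.95])
        full = self.track([0.5, 0.3, 0.2, 0.9])
        out = punt_combine(reduced, full, 0.94)
        # full scores rescaled so their maximum over replaced positions is theta
        assert np.allclose(out.values["c"][:3], np.array([0.5, 0.3, 0.2]) * 0.94 / 0.5)

    def test_invariants_on_random_tracks(self):
        rng = np.random.default_rng(0)
        lay = GenomeLayout({"c": 500})
        theta = 0.7
        reduced = ScoreTrack(lay, 1, {"c": rng.random(500)})
        full = ScoreTrack(lay, 1, {"c": rng.random(500)})
        out = punt_combine(reduced, full, theta)
        replaced = reduced.values["c"] < theta
        # values above theta only from the reduced model
        assert np.all(out.values["c"][replaced] <= theta + 1e-12)
        assert np.array_equal(out.values["c"][~replaced], reduced.values["c"][~replaced])
        # rank order among replaced positions follows the full model
        f = full.values["c"][replaced]
        o = out.values["c"][replaced]
        assert np.array_equal(np.argsort(f, kind="stable"), np.argsort(o, kind="stable"))
        assert out.values["c"].min() >= 0 and out.values["c"].max() <= 1

    def test_errors(self):
        reduced = self.track([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="theta"):
            punt_combine(reduced, reduced, 1.5)
        other = ScoreTrack(GenomeLayout({"d": 4}), 1, {"d": np.zeros(4)})
        with pytest.raises(ValueError, match="mismatch"):
            punt_combine(reduced, other, 0.9)


class TestModelResults:
    def test_fit_and_summary(self):
        rng = np.random.default_rng(0)
        n = 120
        y = np.arange(n) % 3 == 0
        cols = {
            "good": y + rng.normal(0, 0.2, n),
            "ok": y + rng.normal(0, 0.8, n),
            "junk": rng.random(n),
        }
        cols = {k: (v - v.min()) / (v.max() - v.min()) for k, v in cols.items()}
        m = FeatureMatrix(pd.DataFrame(cols), y, [("chr1", i) for i in range(n)])
        res = PuntingEnsemble(m, k_reduced=2).fit(cv_auc_folds=3)
        assert res.reduced_features == ["good", "ok"]
        text = res.summary()
        assert "good" in text and "theta" in text and "CV AUC" in text

    def test_predict_matrix_combined_respects_theta(self):
        m = toy_matrix(n=80, separation=2.0)
        res = PuntingEnsemble(m, k_reduced=1, theta=0.8).fit()
        out = res.predict_matrix(m.data)
        low = out["reduced"] < 0.8
        assert np.all(out.loc[low, "combined"] <= 0.8 + 1e-12)
        assert np.all(out.loc[~low, "combined"] == out.loc[~low, "reduced"])

    def test_save_load_roundtrip(self, tmp_path):
        from tssensemble import PuntingEnsembleResults

        m = toy_matrix(n=60)
        res = PuntingEnsemble(m, k_reduced=1).fit()
        path = tmp_path / "model.pkl"
        res.save(path)
        back = PuntingEnsembleResults.load(path)
        assert back.reduced_features == res.reduced_features
        assert np.array_equal(
            back.full_model.predict_proba(m.data), res.full_model.predict_proba(m.data)
        )
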