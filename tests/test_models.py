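"""Classifiers, metrics, balanced sampling, importance ranking."""

import numpy as np
import pytest
from scipy.stats import chisquare

from pdlscreen import models as M
from pdlscreen.models import (ClassificationMetrics, ModelConfig, ModelError,
                              confusion_metrics, cross_validate,
                              feature_importance, oob_metrics, predict_proba,
                              select_top_k, train_mlp, train_rf, train_svm)


def _bit_rule_matrix(n=800, n_features=40, seed=0):
    """Random bit matrix where the label is bit0 AND (bit1 OR bit2)."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, n_features)) < 0.5).astype(np.uint8)
    y = (X[:, 0] & (X[:, 1] | X[:, 2])).astype(int)
    return X, y


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics(["active", "inactive", "active"],
                              ["active", "inactive", "active"])
        assert (m.se, m.sp, m.q, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_inactive_predictions_degenerate(self):
        m = confusion_metrics(["active", "inactive", "inactive"],
                              ["inactive"] * 3)
        assert m.se == 0.0 and m.mcc == 0.0  # zero factor -> 0 by convention

    def test_formula_oracle(self):
        # tp=2 fp=1 tn=3 fn=1 -> mcc = (6-1)/sqrt(3*3*4*4) = 5/12
        m = ClassificationMetrics(tp=2, tn=3, fp=1, fn=1)
        assert m.mcc == pytest.approx(5 / 12)
        assert m.se == pytest.approx(2 / 3)
        assert m.sp == pytest.approx(3 / 4)
        assert m.q == pytest.approx(5 / 7)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(1)
        yt = rng.integers(0, 2, 60)
        yp = rng.integers(0, 2, 60)
        direct = confusion_metrics(yt, yp).mcc
        swapped = confusion_metrics(1 - yt, 1 - yp).mcc
        assert direct == pytest.approx(swapped)

    def test_empty_input(self):
        with pytest.raises(ModelError):
            confusion_metrics([], [])

    def test_unknown_label(self):
        with pytest.raises(ModelError):
            confusion_metrics(["maybe"], ["active"])


class TestBalancedForest:
    def test_bags_are_class_balanced(self, clean_dataset, clean_forest):
        y = M._as_binary(clean_dataset.observed_labels())
        n_min = int(min(np.bincount(y)))
        counts = []
        for bag in clean_forest.estimator.bags_:
            counts.append((int(np.sum(y[bag] == 1)), int(np.sum(y[bag] == 0))))
        actives, inactives = zip(*counts)
        # every bag draws the minority-class size from each class
        assert set(actives) == {n_min} and set(inactives) == {n_min}
        stat = chisquare([sum(actives), sum(inactives)])
        assert stat.pvalue > 0.01

    def test_planted_rule_recovery(self, clean_dataset, clean_forest):
        assert oob_metrics(clean_forest).mcc >= 0.9

    def test_shuffled_labels_are_null(self, clean_dataset, clean_morgan):
        _, X = clean_morgan
        y = list(clean_dataset.observed_labels())
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ys = list(y)
            rng.shuffle(ys)
            model = train_rf(X, ys, ModelConfig(n_trees=200, seed=seed))
            assert abs(oob_metrics(model).mcc) < 0.1

    def test_reproducible_for_fixed_seed(self, clean_dataset, clean_morgan):
        _, X = clean_morgan
        y = clean_dataset.observed_labels()
        m1 = train_rf(X, y, ModelConfig(n_trees=50, seed=9))
        m2 = train_rf(X, y, ModelConfig(n_trees=50, seed=9))
        assert np.array_equal(m1.oob_pred, m2.oob_pred)

    def test_oob_converges_with_forest_size(self, clean_dataset, clean_morgan):
        _, X = clean_morgan
        y = clean_dataset.observed_labels()
        mcc_500 = oob_metrics(train_rf(X, y, ModelConfig(n_trees=500, seed=2))).mcc
        mcc_1000 = oob_metrics(train_rf(X, y, ModelConfig(n_trees=1000, seed=2))).mcc
        assert abs(mcc_500 - mcc_1000) < 0.02

    def test_tiny_class_rejected(self):
        X = np.eye(4)
        with pytest.raises(ModelError, match="2 molecules per class"):
            train_rf(X, ["active", "inactive", "inactive", "inactive"],
                     ModelConfig(n_trees=10))

    def test_vote_fraction_probability_oracle(self, clean_morgan,
                                              clean_dataset, clean_forest):
        # probability must equal the literal fraction of trees voting active
        _, X = clean_morgan
        rows = X[:15]
        proba = predict_proba(clean_forest, rows)
        votes = np.zeros(len(rows))
        for tree in clean_forest.estimator.trees_:
            votes += tree.predict(rows.astype(np.float32))
        assert np.array_equal(proba, votes / len(clean_forest.estimator.trees_))
        assert np.all((proba >= 0) & (proba <= 1))


class TestImportance:
    def test_informative_bits_rank_top(self):
        X, y = _bit_rule_matrix()
        model = train_rf(X, y, ModelConfig(n_trees=300, seed=5))
        ranking = feature_importance(model)
        top10 = set(ranking.names[:10])
        assert {"F00000", "F00001", "F00002"} <= top10
        # noise features score below the informative ones
        informative = ranking.scores[[ranking.names.index(f)
                                      for f in ("F00000", "F00001", "F00002")]]
        noise = [s for n, s in zip(ranking.names, ranking.scores)
                 if n not in ("F00000", "F00001", "F00002")]
        assert informative.min() > np.mean(np.abs(noise))

    def test_deterministic_ranking(self):
        X, y = _bit_rule_matrix(n=300)
        model = train_rf(X, y, ModelConfig(n_trees=100, seed=3))
        r1 = feature_importance(model, seed=1)
        r2 = feature_importance(model, seed=1)
        assert r1.names == r2.names
        assert np.array_equal(r1.scores, r2.scores)

    def test_requires_forest(self):
        X, y = _bit_rule_matrix(n=100)
        svm = train_svm(X, y, ModelConfig(family="svm", seed=0))
        with pytest.raises(ModelError):
            feature_importance(svm)

    def test_select_top_k(self):
        X, y = _bit_rule_matrix(n=300)
        model = train_rf(X, y, ModelConfig(n_trees=100, seed=3))
        ranking = feature_importance(model)
        assert len(select_top_k(ranking, 5)) == 5
        assert select_top_k(ranking, len(ranking.names)) == ranking.names
        with pytest.raises(ModelError):
            select_top_k(ranking, 0)
        with pytest.raises(ModelError):
            select_top_k(ranking, len(ranking.names) + 1)

    def test_topk_model_matches_full_model(self, clean_dataset, clean_morgan,
                                           clean_forest):
        _, X = clean_morgan
        y = clean_dataset.observed_labels()
        ranking = feature_importance(clean_forest)
        keep = select_top_k(ranking, 50)
        manifest = clean_forest.column_manifest
        cols = [manifest.index(c) for c in keep]
        small = train_rf(np.ascontiguousarray(X[:, cols]), y,
                         ModelConfig(n_trees=300, seed=11))
        assert abs(oob_metrics(small).mcc
                   - oob_metrics(clean_forest).mcc) <= 0.05


class TestSvm:
    def test_separable_toy_set(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (30, 4)),
                       rng.normal(3, 0.3, (30, 4))])
        y = [0] * 30 + [1] * 30
        model = train_svm(X, y, ModelConfig(family="svm", seed=0))
        pred = (predict_proba(model, X) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    def test_grid_search_finds_in_range_optimum(self):
        from sklearn.model_selection import GridSearchCV
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X, y = _bit_rule_matrix(n=300, seed=4)
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf", class_weight="balanced"))])
        grid = GridSearchCV(
            pipe,
            {"svc__C": [1.0, M.DEFAULT_SVM_C, 50.0],
             "svc__gamma": [1e-4, M.DEFAULT_SVM_GAMMA, 1e-2]},
            cv=10, scoring="accuracy").fit(X, y)
        assert 1.0 <= grid.best_params_["svc__C"] <= 50.0
        assert 1e-4 <= grid.best_params_["svc__gamma"] <= 1e-2

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            train_svm(np.eye(4), [1, 1, 1, 1], ModelConfig(family="svm"))


class TestMlp:
    def test_planted_rule_held_out(self, clean_dataset, clean_morgan):
        _, X = clean_morgan
        y = M._as_binary(clean_dataset.observed_labels())
        rng = np.random.default_rng(0)
        order = rng.permutation(len(y))
        cut = int(0.8 * len(y))
        tr, te = order[:cut], order[cut:]
        config = ModelConfig(family="mlp", seed=0, epochs=150)
        model = train_mlp(X[tr], y[tr], config)
        pred = (predict_proba(model, X[te]) >= 0.5).astype(int)
        assert confusion_metrics(y[te], pred).mcc >= 0.8

    def test_constant_features_collapse_to_majority(self):
        X = np.ones((60, 5))
        y = [1] * 10 + [0] * 50
        model = train_mlp(X, y, ModelConfig(family="mlp", seed=1, epochs=30))
        pred = (predict_proba(model, X) >= 0.5).astype(int)
        assert np.all(pred == 0)

    def test_nonfinite_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ModelError):
            train_mlp(X, [0, 1] * 5, ModelConfig(family="mlp", epochs=10))


class TestCrossValidate:
    def test_perfect_rule_pools_to_high_mcc(self):
        X, y = _bit_rule_matrix(n=400, seed=2)
        metrics = cross_validate(ModelConfig(family="rf", n_trees=100, seed=0),
                                 X, y, folds=5, seed=0)
        assert metrics.mcc >= 0.9

    def test_shuffled_labels_are_null(self):
        X, y = _bit_rule_matrix(n=400, seed=2)
        rng = np.random.default_rng(0)
        ys = rng.permutation(y)
        metrics = cross_validate(ModelConfig(family="rf", n_trees=100, seed=0),
                                 X, ys, folds=5, seed=0)
        assert abs(metrics.mcc) < 0.15

    def test_minimal_fold_boundary(self):
        X = np.vstack([np.zeros((4, 3)), np.ones((4, 3))])
        y = [0] * 4 + [1] * 4
        metrics = cross_validate(ModelConfig(family="rf", n_trees=20, seed=0),
                                 X, y, folds=2, seed=0)
        assert metrics.q >= 0.5

    def test_minority_smaller_than_folds(self):
        X = np.eye(12)
        y = [1] * 3 + [0] * 9
        with pytest.raises(ModelError):
            cross_validate(ModelConfig(family="rf", n_trees=10), X, y,
                           folds=10, seed=0)


class TestConfigValidation:
    def test_unknown_family(self):
        with pytest.raises(ModelError):
            ModelConfig(family="gbm")

    def test_nonpositive_hyperparameters(self):
        with pytest.raises(ModelError):
            ModelConfig(n_trees=0)
        with pytest.raises(ModelError):
            ModelConfig(svm_c=-1.0)
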