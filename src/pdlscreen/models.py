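"""Classifier families, class-imbalance handling, metrics and feature ranking.

The activity data is heavily imbalanced (roughly 3 actives per 200
inactives), so the random forest draws, for every tree, a bootstrap sample
containing the *same* number of actives and inactives — the minority-class
size each, sampled with replacement.  Validation uses the out-of-bag (OOB)
mechanism: each molecule is predicted only by the trees whose bootstrap
sample excluded it, and the pooled OOB confusion matrix yields sensitivity
(SE), specificity (SP), overall accuracy (Q) and the Matthews correlation
coefficient (MCC).  Descriptor importance is the permutation-based mean
decrease in accuracy measured on each tree's OOB sample.

The SVM (RBF kernel, balanced class weights) and multilayer-perceptron
(4 × 50 ReLU layers, Adam, log loss) comparators standardize features by
z-score; the forest consumes raw descriptor values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .descriptors import DescriptorMatrix

logger = logging.getLogger(__name__)

#: RBF-SVM hyperparameters from a 10-fold grid search over C in [1, 50] and
#: gamma in [1e-4, 1e-2] on the original activity training data
DEFAULT_SVM_C = 3.593813663804626
DEFAULT_SVM_GAMMA = 0.007742636826811269

POSITIVE = "active"
NEGATIVE = "inactive"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts and derived SE/SP/Q/MCC for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def q(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def mcc(self) -> float:
        factors = [self.tp + self.fp, self.tp + self.fn,
                   self.tn + self.fp, self.tn + self.fn]
        if any(f == 0 for f in factors):
            return 0.0
        num = self.tp * self.tn - self.fp * self.fn
        return num / float(np.sqrt(np.prod([float(f) for f in factors])))

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "se": self.se, "sp": self.sp, "q": self.q, "mcc": self.mcc}


def _as_binary(y: Sequence) -> np.ndarray:
    """Map labels to {1: active, 0: inactive}; accepts strings or ints."""
    arr = np.asarray(y)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    out = np.zeros(len(arr), dtype=int)
    for i, v in enumerate(arr):
        if v == POSITIVE:
            out[i] = 1
        elif v != NEGATIVE:
            raise ModelError(f"unknown label {v!r}")
    return out


def confusion_metrics(y_true: Sequence, y_pred: Sequence) -> ClassificationMetrics:
    """Confusion counts with the active class as positive."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if len(yt) == 0:
        raise ModelError("empty input")
    if len(yt) != len(yp):
        raise ModelError("length mismatch")
    return ClassificationMetrics(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ModelConfig:
    """Hyperparameters for one classifier family (``rf``, ``svm``, ``mlp``)."""

    family: str = "rf"
    seed: int = 0
    # rf
    n_trees: int = 500
    balanced_sampsize: bool = True
    max_features: str | int = "sqrt"
    # svm
    svm_c: float = DEFAULT_SVM_C
    svm_gamma: float = DEFAULT_SVM_GAMMA
    # mlp
    hidden_layers: tuple[int, ...] = (50, 50, 50, 50)
    batch_size: int = 36
    epochs: int = 500

    def __post_init__(self) -> None:
        if self.family not in ("rf", "svm", "mlp"):
            raise ModelError(f"unknown model family {self.family!r}")
        if min(self.n_trees, self.batch_size, self.epochs) <= 0:
            raise ModelError("hyperparameters must be positive")
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ModelError("SVM C and gamma must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier with its column manifest and OOB bookkeeping."""

    config: ModelConfig
    column_manifest: list[str]
    estimator: object
    y_train: np.ndarray | None = None
    oob_proba: np.ndarray | None = None  # rf only: OOB vote fraction active
    oob_pred: np.ndarray | None = None

    @property
    def family(self) -> str:
        return self.config.family


@dataclass
class FeatureRanking:
    """Descriptors ordered by permutation mean-decrease-accuracy importance."""

    names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scores) > 1e-12):
            raise ModelError("scores must be sorted non-increasing")


# ---------------------------------------------------------------------------
# balanced random forest

class BalancedRandomForest:
    """Random forest whose trees see class-balanced bootstrap samples.

    Every tree is grown (unpruned) on a bootstrap draw of ``n_min`` actives
    plus ``n_min`` inactives, each sampled with replacement, where ``n_min``
    is the minority-class size.  Predicted probability is the fraction of
    trees voting active; OOB predictions use only the trees whose draw
    excluded the molecule.
    """

    def __init__(self, n_trees: int = 500, max_features: str | int = "sqrt",
                 seed: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.in_bag_: np.ndarray | None = None  # (n_trees, n) bool
        self.bags_: list[np.ndarray] = []       # per-tree draws, with repeats
        self.oob_proba_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if len(pos) < 2 or len(neg) < 2:
            raise ModelError("need at least 2 molecules per class")
        n_min = min(len(pos), len(neg))
        n = len(y)
        root = np.random.SeedSequence(self.seed)
        tree_seeds = root.generate_state(2 * self.n_trees) % (2 ** 31)

        self.trees_ = []
        self._X_cache = X  # kept for OOB permutation importance
        self.in_bag_ = np.zeros((self.n_trees, n), dtype=bool)
        votes = np.zeros(n)
        counts = np.zeros(n)
        for t in range(self.n_trees):
            rng = np.random.default_rng(tree_seeds[2 * t])
            bag = np.concatenate([rng.choice(pos, n_min, replace=True),
                                  rng.choice(neg, n_min, replace=True)])
            tree = DecisionTreeClassifier(max_features=self.max_features,
                                          random_state=int(tree_seeds[2 * t + 1]))
            tree.fit(X[bag], y[bag])
            self.trees_.append(tree)
            self.bags_.append(bag)
            self.in_bag_[t, bag] = True
            oob = ~self.in_bag_[t]
            if oob.any():
                votes[oob] += tree.predict(X[oob])
                counts[oob] += 1
        with np.errstate(invalid="ignore"):
            self.oob_proba_ = np.where(counts > 0, votes / counts, np.nan)
        never_oob = int(np.sum(counts == 0))
        if never_oob:
            logger.warning("%d molecules were in-bag for every tree; their "
                           "OOB probability is NaN (treated as inactive)",
                           never_oob)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _matrix_values(matrix: DescriptorMatrix | np.ndarray) -> np.ndarray:
    return matrix.values if isinstance(matrix, DescriptorMatrix) else np.asarray(matrix)


def _matrix_columns(matrix: DescriptorMatrix | np.ndarray) -> list[str]:
    if isinstance(matrix, DescriptorMatrix):
        return list(matrix.column_names)
    return [f"F{i:05d}" for i in range(np.asarray(matrix).shape[1])]


def train_rf(matrix: DescriptorMatrix | np.ndarray, labels: Sequence,
             config: ModelConfig | None = None) -> TrainedModel:
    """Fit the balanced random forest and populate OOB predictions."""
    config = config or ModelConfig(family="rf")
    if config.family != "rf":
        raise ModelError("train_rf requires an rf config")
    X = _matrix_values(matrix)
    if not np.all(np.isfinite(X)):
        raise ModelError("descriptor matrix contains non-finite values")
    y = _as_binary(labels)
    forest = BalancedRandomForest(n_trees=config.n_trees,
                                  max_features=config.max_features,
                                  seed=config.seed).fit(X, y)
    oob_proba = forest.oob_proba_
    oob_pred = np.where(np.nan_to_num(oob_proba, nan=0.0) >= 0.5, 1, 0)
    return TrainedModel(config=config, column_manifest=_matrix_columns(matrix),
                        estimator=forest, y_train=y,
                        oob_proba=oob_proba, oob_pred=oob_pred)


def oob_metrics(model: TrainedModel) -> ClassificationMetrics:
    """Pooled confusion metrics over the forest's OOB predictions."""
    if model.family != "rf" or model.oob_pred is None:
        raise ModelError("OOB metrics require a fitted rf model")
    return confusion_metrics(model.y_train, model.oob_pred)


# ---------------------------------------------------------------------------
# importance and selection

def feature_importance(model: TrainedModel, seed: int | None = None,
                       max_oob_rows: int = 500) -> FeatureRanking:
    """Permutation mean-decrease-accuracy importance, averaged over trees.

    For each tree, accuracy on its OOB sample is compared with the accuracy
    after permuting one descriptor column at a time; only descriptors the
    tree actually splits on are permuted (others cannot change its output).
    The per-tree decreases are averaged over all trees.  Deterministic for a
    fixed seed; OOB samples larger than ``max_oob_rows`` are subsampled.
    """
    if model.family != "rf":
        raise ModelError("feature importance requires an rf model")
    forest: BalancedRandomForest = model.estimator  # type: ignore[assignment]
    if forest.in_bag_ is None:
        raise ModelError("forest not fitted")
    X = forest._X_cache
    y = model.y_train
    n_features = X.shape[1]
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    totals = np.zeros(n_features)
    for t, tree in enumerate(forest.trees_):
        oob_idx = np.flatnonzero(~forest.in_bag_[t])
        if len(oob_idx) == 0:
            continue
        if len(oob_idx) > max_oob_rows:
            oob_idx = rng.choice(oob_idx, max_oob_rows, replace=False)
        Xo = X[oob_idx]
        yo = y[oob_idx]
        base_acc = float(np.mean(tree.predict(Xo) == yo))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            col = Xo[:, f].copy()
            Xo[:, f] = rng.permutation(col)
            perm_acc = float(np.mean(tree.predict(Xo) == yo))
            Xo[:, f] = col
            totals[f] += base_acc - perm_acc
    scores = totals / len(forest.trees_)
    order = np.lexsort((np.array(model.column_manifest), -scores))
    return FeatureRanking(names=[model.column_manifest[i] for i in order],
                          scores=scores[order])


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First ``k`` descriptor names of the ranking (stable)."""
    if k <= 0:
        raise ModelError("k must be positive")
    if k > len(ranking.names):
        raise ModelError(f"k={k} exceeds ranking size {len(ranking.names)}")
    return ranking.names[:k]


# ---------------------------------------------------------------------------
# SVM / MLP comparators

def train_svm(matrix: DescriptorMatrix | np.ndarray, labels: Sequence,
              config: ModelConfig | None = None) -> TrainedModel:
    """RBF C-SVM with balanced class weights on z-scored descriptors.

    Probabilities come from Platt scaling (sklearn's built-in calibration).
    """
    config = config or ModelConfig(family="svm")
    X = _matrix_values(matrix)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ModelError("both classes required")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma,
                    class_weight="balanced", probability=True,
                    random_state=config.seed)),
    ]).fit(X, y)
    return TrainedModel(config=config, column_manifest=_matrix_columns(matrix),
                        estimator=pipe, y_train=y)


def train_mlp(matrix: DescriptorMatrix | np.ndarray, labels: Sequence,
              config: ModelConfig | None = None) -> TrainedModel:
    """Four-hidden-layer (50 units each) ReLU perceptron, Adam, log loss.

    Features are z-scored; output is a logistic unit so predicted
    probabilities are the network's sigmoid activations.  Reproducible for a
    fixed seed within the numeric determinism of the backend.
    """
    config = config or ModelConfig(family="mlp")
    X = _matrix_values(matrix)
    if not np.all(np.isfinite(X)):
        raise ModelError("non-finite inputs")
    y = _as_binary(labels)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(hidden_layer_sizes=config.hidden_layers,
                              activation="relu", solver="adam",
                              batch_size=config.batch_size,
                              max_iter=config.epochs,
                              random_state=config.seed)),
    ]).fit(X, y)
    return TrainedModel(config=config, column_manifest=_matrix_columns(matrix),
                        estimator=pipe, y_train=y)


TRAINERS = {"rf": train_rf, "svm": train_svm, "mlp": train_mlp}


def cross_validate(config: ModelConfig, matrix: DescriptorMatrix | np.ndarray,
                   labels: Sequence, folds: int = 10,
                   seed: int = 0) -> ClassificationMetrics:
    """Stratified k-fold CV; metrics from the pooled out-of-fold confusion."""
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ModelError("folds must be >= 2")
    X = _matrix_values(matrix)
    y = _as_binary(labels)
    if min(np.bincount(y)) < folds:
        raise ModelError("minority class smaller than fold count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y)
    for train_idx, test_idx in skf.split(X, y):
        model = TRAINERS[config.family](X[train_idx], y[train_idx], config)
        y_pred[test_idx] = (predict_proba(model, X[test_idx]) >= 0.5).astype(int)
    return confusion_metrics(y, y_pred)


def predict_proba(model: TrainedModel,
                  matrix: DescriptorMatrix | np.ndarray) -> np.ndarray:
    """Probability of the active class for every row of ``matrix``.

    A :class:`DescriptorMatrix` is aligned to the model's column manifest
    (extra columns allowed, missing columns are an error); a bare array must
    already match the manifest width.
    """
    if isinstance(matrix, DescriptorMatrix):
        matrix = matrix.subset_columns(model.column_manifest)
        X = matrix.values
    else:
        X = np.asarray(matrix)
        if X.shape[1] != len(model.column_manifest):
            raise ModelError("matrix width does not match column manifest")
    if model.family == "rf":
        return model.estimator.predict_proba(X)  # vote fraction
    return model.estimator.predict_proba(X)[:, 1]
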