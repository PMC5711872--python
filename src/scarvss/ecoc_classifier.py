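"""One-vs-one error-correcting output codes (ECOC) classification.

A coding matrix with K rows (classes) and K(K-1)/2 columns (one per
unordered class pair) reduces the multiclass problem to binary ones: for
the column of pair (i, j) with i < j, class i is coded +1, class j is -1
and every other class 0.  Each binary learner is trained only on the
samples of its two classes.  A new sample is assigned to the class k that
minimizes the loss-weighted decoding objective

    sum_l |m_kl| g(m_kl s_l)  /  sum_l |m_kl|

where s_l is learner l's score and g is the binary loss: the hinge loss
``max(0, 1-z)/2`` for margin learners (SVM, LDA) and the Hamming loss
``(1 - sign(z))/2`` for hard-vote learners (1-NN, naive Bayes).  Ties
resolve to the smallest class label.

Available binary learners: ``knn1`` (1-nearest-neighbor, Euclidean,
implemented natively, distance ties to the earliest training sample),
``linear_svm`` (soft margin, C=1), ``grid_svm`` (RBF SVM with C and kernel
width chosen by inner 5-fold cross-validated grid search — a deterministic
stand-in for Bayesian hyperparameter optimization), ``lda`` and ``gnb``.

The leave-one-out (LOO) harness trains on N-1 samples and predicts the
held-out one, for every sample in turn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .feature_pipeline import (
    FeatureMatrix,
    apply_standardization,
    standardization_stats,
)

log = logging.getLogger(__name__)

LEARNER_SPECS = ("knn1", "linear_svm", "grid_svm", "lda", "gnb")
#: Learners whose score is a signed margin (decoded with the hinge loss);
#: the rest emit hard +/-1 votes (decoded with the Hamming loss).
MARGIN_LEARNERS = frozenset({"linear_svm", "grid_svm", "lda"})

#: grid_svm search space: soft-margin constant C and Gaussian kernel width
#: sigma (gamma = 1 / (2 sigma^2)).
GRID_SVM_C = (0.01, 0.1, 1.0, 10.0, 100.0)
GRID_SVM_WIDTH = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class CodingMatrix:
    """K x B matrix with entries in {-1, 0, +1}; rows follow class_order."""

    matrix: np.ndarray
    class_order: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_learners(self) -> int:
        return self.matrix.shape[1]


def build_ovo_coding(labels) -> CodingMatrix:
    """One-vs-one coding: one column per unordered class pair (i < j) in
    lexicographic order, class i coded +1 and class j coded -1."""
    class_order = np.unique(np.asarray(labels))
    K = class_order.size
    if K < 2:
        raise ValueError(f"need at least 2 distinct classes, got {K}")
    B = K * (K - 1) // 2
    matrix = np.zeros((K, B), dtype=np.int8)
    col = 0
    for a in range(K):
        for b in range(a + 1, K):
            matrix[a, col] = 1
            matrix[b, col] = -1
            col += 1
    return CodingMatrix(matrix=matrix, class_order=class_order)


class _NearestNeighbor1:
    """1-NN with Euclidean distance; distance ties resolve to the earliest
    training sample (deterministic)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestNeighbor1":
        self._X = np.asarray(X, dtype=np.float64)
        self._y = np.asarray(y)
        return self

    def vote(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)  # argmin takes the first minimum
        return self._y[nearest]


class _BinaryLearner:
    """One trained binary learner with a uniform score interface.

    ``score(X)`` returns a signed value per sample: a real margin for
    margin learners, a hard +/-1 vote otherwise.  Positive means the +1
    class of the learner's coding column.
    """

    def __init__(self, spec: str, seed: int = 0):
        if spec not in LEARNER_SPECS:
            raise ValueError(f"unknown learner spec {spec!r}; choose from {LEARNER_SPECS}")
        self.spec = spec
        self.seed = seed
        self._est = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BinaryLearner":
        y = np.asarray(y)
        if set(np.unique(y)) != {-1, 1}:
            raise ValueError("binary learner needs both +1 and -1 samples")
        if self.spec == "knn1":
            self._est = _NearestNeighbor1().fit(X, y)
        elif self.spec == "linear_svm":
            self._est = SVC(kernel="linear", C=1.0).fit(X, y)
        elif self.spec == "grid_svm":
            gammas = [1.0 / (2.0 * w**2) for w in GRID_SVM_WIDTH]
            min_class = min(np.sum(y == 1), np.sum(y == -1))
            n_folds = int(min(5, min_class))
            if n_folds >= 2:
                cv = StratifiedKFold(n_folds, shuffle=True, random_state=self.seed)
                search = GridSearchCV(
                    SVC(kernel="rbf"),
                    {"C": list(GRID_SVM_C), "gamma": gammas},
                    cv=cv,
                    n_jobs=None,
                )
                search.fit(X, y)
                self._est = search.best_estimator_
            else:
                # too few samples for an inner split: fall back to mid-grid
                self._est = SVC(kernel="rbf", C=1.0, gamma=gammas[1]).fit(X, y)
        elif self.spec == "lda":
            self._est = LinearDiscriminantAnalysis().fit(X, y)
        elif self.spec == "gnb":
            self._est = GaussianNB().fit(X, y)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.spec == "knn1":
            return self._est.vote(X).astype(np.float64)
        if self.spec == "gnb":
            return self._est.predict(X).astype(np.float64)
        # sklearn orders classes [-1, +1]; decision_function > 0 => class +1
        return np.asarray(self._est.decision_function(X), dtype=np.float64)


@dataclass
class EcocModel:
    coding: CodingMatrix
    learners: list[_BinaryLearner]
    learner_spec: str
    decoding_loss: str
    n_features: int


def _resolve_xy(fm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fm, FeatureMatrix):
        return fm.values, np.asarray(fm.labels)
    X, y = fm
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def train(fm, spec: str, seed: int = 0, decoding_loss: str | None = None) -> EcocModel:
    """Fit one binary learner per one-vs-one coding column.

    ``fm`` is a :class:`FeatureMatrix` or an ``(X, y)`` pair.  The decoding
    loss defaults to hinge for margin learners and Hamming for vote
    learners.
    """
    X, y = _resolve_xy(fm)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    coding = build_ovo_coding(y)
    for cls in coding.class_order:
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} has no training samples")
    if decoding_loss is None:
        decoding_loss = "hinge" if spec in MARGIN_LEARNERS else "hamming"
    if decoding_loss not in ("hinge", "hamming"):
        raise ValueError(f"unknown decoding loss {decoding_loss!r}")

    learners = []
    for col in range(coding.n_learners):
        codes = coding.matrix[:, col]
        pos = coding.class_order[codes == 1][0]
        neg = coding.class_order[codes == -1][0]
        mask = (y == pos) | (y == neg)
        y_bin = np.where(y[mask] == pos, 1, -1)
        learners.append(_BinaryLearner(spec, seed=seed).fit(X[mask], y_bin))
    return EcocModel(
        coding=coding,
        learners=learners,
        learner_spec=spec,
        decoding_loss=decoding_loss,
        n_features=X.shape[1],
    )


def _binary_loss(z: np.ndarray, loss: str) -> np.ndarray:
    if loss == "hinge":
        return np.maximum(0.0, 1.0 - z) / 2.0
    return (1.0 - np.sign(z)) / 2.0


def decode_losses(model: EcocModel, scores: np.ndarray) -> np.ndarray:
    """Per-class decoding loss for each row of learner scores (N x B)."""
    M = model.coding.matrix.astype(np.float64)  # K x B
    absM = np.abs(M)
    # loss[n, k] = sum_l |m_kl| g(m_kl * s_nl) / sum_l |m_kl|
    z = M[None, :, :] * scores[:, None, :]
    g = _binary_loss(z, model.decoding_loss)
    return (absM[None, :, :] * g).sum(axis=2) / absM.sum(axis=1)[None, :]


def predict(model: EcocModel, X: np.ndarray) -> np.ndarray:
    """Assign each sample to the class minimizing the decoding loss.

    Ties break to the smallest class label (class_order is ascending and
    argmin returns the first minimum).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model's "
            f"{model.n_features}"
        )
    scores = np.column_stack([lrn.score(X) for lrn in model.learners])
    losses = decode_losses(model, scores)
    return model.coding.class_order[losses.argmin(axis=1)]


def loo_cross_validate(
    fm,
    spec: str,
    seed: int = 0,
    *,
    fold_standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out cross-validation: N models, each trained on N-1
    samples, predicting the one held out.  Returns (true, predicted)
    label arrays in input order.

    With ``fold_standardize=True`` the column statistics are re-estimated
    on each training fold and applied to the held-out sample (avoids the
    leakage of the default dataset-wide protocol).
    """
    X, y = _resolve_xy(fm)
    n = X.shape[0]
    K = np.unique(y).size
    if n < K + 1:
        raise ValueError(f"LOO needs at least K+1={K + 1} samples, got {n}")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        x_te = X[i : i + 1]
        if fold_standardize:
            means, sds, zero = standardization_stats(X_tr)
            X_tr = apply_standardization(X_tr, means, sds, zero)
            x_te = apply_standardization(x_te, means, sds, zero)
        model = train((X_tr, y_tr), spec, seed=seed)
        preds[i] = predict(model, x_te)[0]
    return y.copy(), preds
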