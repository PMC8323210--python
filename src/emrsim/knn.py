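"""Personalized kNN disease-status prediction and leave-one-out evaluation.

For each index patient, the training samples are M% of the training pool,
selected at random or by the learned patient similarity or by Euclidean
distance on the numeric representation; the k nearest neighbors within that
subset are found with either the learned similarity or Euclidean distance and
vote with equal weight.  The four named combinations cross the two choices:

    R+L  random training, learned-similarity neighbors
    R+E  random training, Euclidean neighbors
    L+E  learned-similarity training, Euclidean neighbors
    E+L  Euclidean training, learned-similarity neighbors

At M = 100% the training selection is vacuous, so R+L and E+L coincide exactly,
as do R+E and L+E.  Performance is measured by micro-averaged one-vs-rest AUC,
micro F1 (= accuracy for single-label multiclass), and mean cross-entropy loss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import label_binarize

__all__ = [
    "CombinationSpec",
    "PredictionRun",
    "SimilarityKNNClassifier",
    "select_training",
    "knn_predict",
    "loo_evaluate",
    "micro_auc",
    "f1_score",
    "ce_loss",
    "run_combination_grid",
    "scores_to_matrix",
]

_PRESETS = {
    "R+L": ("random", "learned"),
    "R+E": ("random", "euclidean"),
    "L+E": ("learned", "euclidean"),
    "E+L": ("euclidean", "learned"),
}


@dataclass(frozen=True)
class CombinationSpec:
    """One kNN configuration: training-pool selection mode, neighbor metric,
    training fraction M%, neighborhood size k, and the seed used for random
    training selection."""

    training_selection: str = "random"
    neighbor_metric: str = "learned"
    M_percent: float = 100.0
    k: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.training_selection not in ("random", "learned", "euclidean"):
            raise ValueError(f"unknown training selection {self.training_selection!r}")
        if self.neighbor_metric not in ("learned", "euclidean"):
            raise ValueError(f"unknown neighbor metric {self.neighbor_metric!r}")
        if not (0 < self.M_percent <= 100):
            raise ValueError(f"M_percent must lie in (0, 100], got {self.M_percent}")
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    @classmethod
    def from_name(cls, name: str, M_percent: float = 100.0, k: int = 10,
                  seed: int = 0) -> "CombinationSpec":
        if name not in _PRESETS:
            raise ValueError(f"unknown combination {name!r}; choose from {sorted(_PRESETS)}")
        sel, met = _PRESETS[name]
        return cls(training_selection=sel, neighbor_metric=met,
                   M_percent=M_percent, k=k, seed=seed)

    @property
    def name(self) -> str:
        for nm, (sel, met) in _PRESETS.items():
            if (sel, met) == (self.training_selection, self.neighbor_metric):
                return nm
        return f"{self.training_selection}+{self.neighbor_metric}"


@dataclass
class PredictionRun:
    """One leave-one-out evaluation: per-patient class-probability vectors,
    predicted labels, and summary metrics."""

    spec: CombinationSpec
    classes: tuple
    proba: np.ndarray
    pred_labels: np.ndarray
    true_labels: np.ndarray
    auc: float = field(default=math.nan)
    f1: float = field(default=math.nan)
    ce: float = field(default=math.nan)


def scores_to_matrix(pair_table: pd.DataFrame, ids) -> np.ndarray:
    """Square symmetric similarity matrix from a propagated pair table.

    ``pair_table`` must carry ``id_a, id_b, score``; the diagonal is set to 1
    (a patient is maximally similar to itself)."""
    pos = {pid: i for i, pid in enumerate(ids)}
    S = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(S, 1.0)
    for a, b, s in zip(pair_table["id_a"], pair_table["id_b"], pair_table["score"]):
        if a in pos and b in pos:
            S[pos[a], pos[b]] = s
            S[pos[b], pos[a]] = s
    if np.isnan(S).any():
        raise ValueError("pair table does not cover all patient pairs")
    return S


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_training(pool, index, spec: CombinationSpec, S=None, X=None):
    """Select the M% training subset from the pool for one index patient.

    ``pool`` and ``index`` are integer positions; ``S`` is the full learned
    similarity matrix and ``X`` the numeric representation matrix (each needed
    only for the corresponding selection mode).  The subset size is
    round(M% · |pool|), floored at k (with a warning); a pool smaller than k
    is an error.  Ties in the similarity/distance orderings are broken by
    canonical (ascending) position.
    """
    pool = np.asarray(pool)
    npool = pool.size
    if npool < spec.k:
        raise ValueError(
            f"training pool of {npool} is smaller than k = {spec.k}; "
            "reduce k or enlarge the cohort"
        )
    size = _round_half_up(spec.M_percent / 100.0 * npool)
    if size < spec.k:
        warnings.warn(
            f"M = {spec.M_percent}% yields {size} < k = {spec.k} training "
            f"samples; flooring the subset size at k"
        )
        size = spec.k
    size = min(size, npool)
    pool_sorted = np.sort(pool)
    if size == npool:
        return pool_sorted
    if spec.training_selection == "random":
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))
        return np.sort(rng.choice(pool_sorted, size=size, replace=False))
    if spec.training_selection == "learned":
        if S is None:
            raise ValueError("learned training selection needs the similarity matrix")
        order = np.lexsort((pool_sorted, -S[index, pool_sorted]))
    else:  # euclidean
        if X is None:
            raise ValueError("euclidean training selection needs numeric representations")
        d = np.linalg.norm(X[pool_sorted] - X[index], axis=1)
        order = np.lexsort((pool_sorted, d))
    return np.sort(pool_sorted[order[:size]])


class SimilarityKNNClassifier(BaseEstimator, ClassifierMixin):
    """kNN classifier over a precomputed patient similarity or a numeric
    feature space.

    With ``metric="precomputed"``, ``fit`` takes the training positions' labels
    and ``predict_proba`` a (n_test, n_train) matrix of similarities (higher =
    nearer).  With ``metric="euclidean"``, ``fit(X, y)`` stores the numeric
    training matrix and test rows are compared by Euclidean distance.  Class
    probabilities are the neighbor vote fractions; predicted-label ties are
    broken by larger summed neighbor similarity (smaller summed distance), then
    canonical class order.
    """

    def __init__(self, k: int = 10, metric: str = "euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        y = np.asarray(y)
        if self.metric == "precomputed":
            self._X = None
            self._n_train = y.shape[0]
        elif self.metric == "euclidean":
            self._X = np.asarray(X, dtype=float)
            if self._X.shape[0] != y.shape[0]:
                raise ValueError("X and y lengths disagree")
            self._n_train = y.shape[0]
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self._n_train < self.k:
            raise ValueError(f"training set of {self._n_train} smaller than k = {self.k}")
        self._y = y
        self.classes_ = np.array(sorted(set(y.tolist())))
        return self

    def _affinity(self, X):
        """Rows of 'higher = nearer' affinity between test and train samples."""
        if self.metric == "precomputed":
            A = np.asarray(X, dtype=float)
            if A.shape[1] != self._n_train:
                raise ValueError("similarity matrix does not match training size")
            return A
        X = np.asarray(X, dtype=float)
        d = np.sqrt(((X[:, None, :] - self._X[None, :, :]) ** 2).sum(-1))
        return -d

    def predict_proba(self, X):
        A = self._affinity(X)
        k = self.k
        probs = np.zeros((A.shape[0], self.classes_.size))
        self._tie_break_ = np.zeros_like(probs)
        for i in range(A.shape[0]):
            order = np.lexsort((np.arange(self._n_train), -A[i]))
            nb = order[:k]
            for j, c in enumerate(self.classes_):
                mask = self._y[nb] == c
                probs[i, j] = mask.sum() / k
                self._tie_break_[i, j] = A[i, nb[mask]].sum() if mask.any() else -np.inf
        return probs

    def predict(self, X):
        probs = self.predict_proba(X)
        out = []
        for i in range(probs.shape[0]):
            best = probs[i].max()
            cand = np.flatnonzero(probs[i] == best)
            if cand.size > 1:
                aff = self._tie_break_[i, cand]
                cand = cand[aff == aff.max()]
            out.append(self.classes_[cand[0]])  # canonical class order last
        return np.array(out)


def knn_predict(index, training, spec: CombinationSpec, labels, S=None, X=None,
                classes=None):
    """Class-probability vector and predicted label for one index patient.

    ``training`` holds integer positions; neighbors are the top k by the
    spec's neighbor metric.
    """
    training = np.asarray(training)
    labels = np.asarray(labels)
    clf = SimilarityKNNClassifier(
        k=spec.k,
        metric="precomputed" if spec.neighbor_metric == "learned" else "euclidean",
    )
    if spec.neighbor_metric == "learned":
        if S is None:
            raise ValueError("learned neighbor metric needs the similarity matrix")
        clf.fit(None, labels[training])
        row = S[index, training][None, :]
    else:
        if X is None:
            raise ValueError("euclidean neighbor metric needs numeric representations")
        clf.fit(X[training], labels[training])
        row = X[index][None, :]
    if classes is not None:
        # align probability columns with the full class list
        probs_local = clf.predict_proba(row)[0]
        probs = np.zeros(len(classes))
        for j, c in enumerate(clf.classes_):
            probs[list(classes).index(c)] = probs_local[j]
    else:
        classes = tuple(clf.classes_)
        probs = clf.predict_proba(row)[0]
    label = clf.predict(row)[0]
    return probs, label


def micro_auc(proba, true_labels, classes=None) -> float:
    """Micro-averaged one-vs-rest ROC AUC.

    2-D ``proba``: one-vs-rest (label, score) pairs for every class are pooled
    and a single AUC computed on the pool (ties count 1/2, the Mann-Whitney
    convention).  1-D ``proba``: plain binary AUC of positive-class scores.
    """
    true_labels = np.asarray(true_labels)
    if len(set(true_labels.tolist())) < 2:
        raise ValueError("micro AUC needs at least 2 distinct true labels")
    proba = np.asarray(proba, dtype=float)
    if proba.ndim == 1:
        return float(roc_auc_score(true_labels, proba))
    if classes is None:
        classes = sorted(set(true_labels.tolist()))
    Y = label_binarize(true_labels, classes=list(classes))
    if Y.shape[1] == 1:  # label_binarize collapses the binary case
        Y = np.column_stack([1 - Y[:, 0], Y[:, 0]])
    return float(roc_auc_score(Y.ravel(), proba.ravel()))


def f1_score(pred_labels, true_labels, average: str = "micro") -> float:
    """Micro-averaged F1 over the classes (equals accuracy for single-label
    multiclass); macro available via ``average='macro'``."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("predicted and true label arrays differ in length")
    return float(_sk_f1(true_labels, pred_labels, average=average))


def ce_loss(proba, true_labels, classes=None, eps: float = 1e-15) -> float:
    """Mean cross-entropy −(1/N) Σ ln p(true class), with probabilities
    clipped below at ``eps`` (vote fractions can be exactly zero)."""
    proba = np.asarray(proba, dtype=float)
    true_labels = np.asarray(true_labels)
    if classes is None:
        classes = sorted(set(true_labels.tolist()))
    idx = {c: j for j, c in enumerate(classes)}
    p_true = np.array([proba[i, idx[t]] for i, t in enumerate(true_labels)])
    return float(-np.mean(np.log(np.clip(p_true, eps, 1.0))))


def loo_evaluate(labels, spec: CombinationSpec, S=None, X=None) -> PredictionRun:
    """Leave-one-out evaluation: each patient in turn is the test sample, the
    rest form the training pool; training subset and neighbors follow ``spec``.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < spec.k + 1:
        raise ValueError(f"cohort of {n} too small for k = {spec.k} leave-one-out")
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        warnings.warn("fewer than 2 classes present in the cohort")
    proba = np.zeros((n, len(classes)))
    preds = np.empty(n, dtype=object)
    all_idx = np.arange(n)
    for i in range(n):
        pool = all_idx[all_idx != i]
        training = select_training(pool, i, spec, S=S, X=X)
        probs, label = knn_predict(i, training, spec, labels, S=S, X=X,
                                   classes=classes)
        proba[i] = probs
        preds[i] = label
    run = PredictionRun(spec=spec, classes=classes, proba=proba,
                        pred_labels=preds, true_labels=labels)
    if len(classes) >= 2:
        run.auc = micro_auc(proba, labels, classes=classes)
    run.f1 = f1_score(preds, labels)
    run.ce = ce_loss(proba, labels, classes=classes)
    return run


def run_combination_grid(labels, combinations, M_grid, k: int = 10, seed: int = 0,
                         S=None, X=None):
    """One leave-one-out run per (combination, M) cell.

    Returns ``(results, runs)``: a tidy DataFrame with columns
    (combination, M, auc, f1, ce) and the underlying :class:`PredictionRun`
    objects keyed by (combination, M).
    """
    rows = []
    runs = {}
    for name in combinations:
        for M in M_grid:
            spec = CombinationSpec.from_name(name, M_percent=M, k=k, seed=seed)
            run = loo_evaluate(labels, spec, S=S, X=X)
            runs[(name, M)] = run
            rows.append({"combination": name, "M": M,
                         "auc": run.auc, "f1": run.f1, "ce": run.ce})
    return pd.DataFrame(rows), runs
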