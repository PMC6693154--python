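"""Alignment-quality metrics.

* KNN cross-condition label transfer: a classifier fit on one condition's
  embeddings labels the cells of the other condition(s).
* Alignment score: after downsampling every condition to the smallest one,
  how few of each cell's k nearest neighbors come from its own condition,
  rescaled so 1 = perfectly mixed and 0 = fully separated.
* Composite accuracy = transfer accuracy x alignment score.
* Interpolation accuracy: ten-fold CV of a KNN classifier on real
  expression, and the same classifier's accuracy on interpolated profiles.
* Mean silhouette coefficient of cell-type clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import KFold

from .aligner import AlignmentModel, embed_cells
from .dataset import UNLABELED, ExpressionDataset


@dataclass
class EvaluationReport:
    label_accuracy: float
    alignment_score: float
    composite: float
    per_class_accuracy: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        assert abs(self.composite - self.label_accuracy * self.alignment_score) < 1e-12


def knn_predict(E_train: np.ndarray, labels_train, E_test: np.ndarray, k: int):
    """Majority-vote KNN with deterministic tie-breaking: ties go to the
    candidate class with the smallest mean neighbor distance, then to the
    lexicographically smallest class name."""
    E_train = np.asarray(E_train, dtype=np.float64)
    E_test = np.asarray(E_test, dtype=np.float64)
    labels_train = np.asarray(labels_train, dtype=object)
    if E_train.shape[0] == 0 or E_test.shape[0] == 0:
        raise ValueError("empty inputs")
    if k > E_train.shape[0]:
        raise ValueError(f"k={k} exceeds training size {E_train.shape[0]}")
    D = cdist(E_test, E_train)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = np.empty(E_test.shape[0], dtype=object)
    for i in range(E_test.shape[0]):
        nbr = order[i]
        votes = {}
        for j in nbr:
            votes.setdefault(labels_train[j], []).append(D[i, j])
        best = max(votes)
        best_key = None
        for cls in sorted(votes):
            key = (-len(votes[cls]), float(np.mean(votes[cls])), str(cls))
            if best_key is None or key < best_key:
                best_key, best = key, cls
        out[i] = best
    return out


def knn_transfer_accuracy(E_train, labels_train, E_test, labels_test,
                          k: int = 5) -> float:
    pred = knn_predict(E_train, labels_train, E_test, k)
    labels_test = np.asarray(labels_test, dtype=object)
    return float(np.mean(pred == labels_test))


def alignment_score(E: np.ndarray, condition_of, k: int | None = None,
                    seed: int = 0) -> float:
    """Mixing statistic in [0, 1].

    Every condition is downsampled to the smallest condition's size; for
    each cell, x_i counts its k nearest neighbors (self excluded) from its
    own condition.  The score 1 - (mean(x) - k/C) / (k - k/C), with C the
    number of conditions, is 1 under perfect mixing and 0 under complete
    separation; clipped to [0, 1].
    """
    E = np.asarray(E, dtype=np.float64)
    condition_of = np.asarray(condition_of, dtype=object)
    conds = sorted(set(condition_of))
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    smallest = min(int((condition_of == c).sum()) for c in conds)
    keep = []
    for c in conds:
        idx = np.flatnonzero(condition_of == c)
        keep.append(rng.choice(idx, size=smallest, replace=False))
    keep = np.concatenate(keep)
    Es, cs = E[keep], condition_of[keep]
    n = len(keep)
    if k is None:
        k = max(10, round(0.01 * n))
    if k >= n:
        raise ValueError(f"k={k} must be below downsampled total {n}")
    D = cdist(Es, Es)
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    same = (cs[nbrs] == cs[:, None]).sum(axis=1)
    expected = k / len(conds)
    score = 1.0 - (same.mean() - expected) / (k - expected)
    return float(np.clip(score, 0.0, 1.0))


def _labels_for(ds: ExpressionDataset, labels):
    out = np.asarray(labels if labels is not None else ds.type_of, dtype=object)
    return out


def composite_accuracy(model: AlignmentModel, ds: ExpressionDataset,
                       labels=None, *, train_condition: str | None = None,
                       k_neighbors: int = 5, alignment_k: int | None = None,
                       seed: int = 0) -> EvaluationReport:
    """Pairwise or multi-way composite accuracy on the embedded dataset.

    Two conditions: label the second condition using the first (default
    train_condition = lexicographically first, the "control").  Three or
    more: sweep every condition as the representative that labels all
    others, and average the accuracies.  Composite = accuracy x alignment
    score.
    """
    labels = _labels_for(ds, labels)
    E = embed_cells(model, ds)
    conds = ds.conditions
    cond_of = ds.condition_of

    def _transfer(train_cond):
        tr = cond_of == train_cond
        te = ~tr
        if np.any(labels[tr] == UNLABELED):
            raise ValueError(f"unlabeled cells in training condition {train_cond!r}")
        pred = knn_predict(E[tr], labels[tr], E[te], k_neighbors)
        truth = labels[te]
        acc = float(np.mean(pred == truth))
        per_class = {
            c: float(np.mean(pred[truth == c] == c))
            for c in sorted(set(truth)) if c != UNLABELED
        }
        return acc, per_class

    if len(conds) == 2:
        train_cond = train_condition if train_condition is not None else conds[0]
        acc, per_class = _transfer(train_cond)
    else:
        accs, per_class = [], {}
        for c in conds:
            a, pc = _transfer(c)
            accs.append(a)
            for cls, v in pc.items():
                per_class.setdefault(cls, []).append(v)
        acc = float(np.mean(accs))
        per_class = {cls: float(np.mean(v)) for cls, v in per_class.items()}

    score = alignment_score(E, cond_of, k=alignment_k, seed=seed)
    return EvaluationReport(
        label_accuracy=acc, alignment_score=score, composite=acc * score,
        per_class_accuracy=per_class,
        params={"k_neighbors": k_neighbors, "alignment_k": alignment_k,
                "seed": seed,
                "train_condition": train_condition},
    )


def interpolation_accuracy(expression: np.ndarray, labels,
                           interpolated: np.ndarray,
                           interpolated_labels=None, k: int = 5,
                           n_folds: int = 10, seed: int = 0):
    """Ten-fold CV: per fold, fit KNN on 90% of real expression, report (a)
    accuracy on the held-out 10% and (b) accuracy labeling all interpolated
    cells; both averaged over folds."""
    expression = np.asarray(expression, dtype=np.float64)
    interpolated = np.asarray(interpolated, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if expression.shape[1] != interpolated.shape[1]:
        raise ValueError("gene spaces differ")
    if expression.shape[0] < n_folds:
        raise ValueError("fewer cells than folds")
    if interpolated_labels is None:
        if interpolated.shape[0] != expression.shape[0]:
            raise ValueError("provide interpolated_labels when cell sets differ")
        interpolated_labels = labels
    interpolated_labels = np.asarray(interpolated_labels, dtype=object)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    expr_accs, interp_accs = [], []
    for tr, te in kf.split(expression):
        kk = min(k, len(tr))
        expr_accs.append(
            knn_transfer_accuracy(expression[tr], labels[tr],
                                  expression[te], labels[te], k=kk))
        interp_accs.append(
            knn_transfer_accuracy(expression[tr], labels[tr],
                                  interpolated, interpolated_labels, k=kk))
    return float(np.mean(expr_accs)), float(np.mean(interp_accs))


def silhouette_coefficient(E: np.ndarray, labels) -> float:
    """Mean Euclidean silhouette; singleton classes contribute 0 (warned)."""
    E = np.asarray(E, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (counts == 1).any():
        warnings.warn("singleton class present; its silhouette is 0")
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[l] for l in labels], dtype=int)
    return float(np.mean(silhouette_samples(E, codes)))
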