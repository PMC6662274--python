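"""Biomarker predictors: ReliefF ranking plus a 1-nearest-neighbour
classifier under one-minus-cosine distance, with nested top-k model selection
by stratified cross-validation and held-out ROC/AUC evaluation.

Two binary tasks are supported:

* ``aging`` — normal samples only; label 1 if age > 50 years, else 0;
* ``disease`` — all samples; label 1 for AD, 0 for normal.

ReliefF weights each gene by how well it separates a sample from its nearest
neighbours of the other class relative to its own class; genes are then
ranked by weight and the nested models "top-1 genes", "top-2 genes", ...,
"top-``top_models`` genes" are compared by cross-validated accuracy of the
nearest-neighbour classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .data_model import ExpressionMatrix

__all__ = [
    "RankedGeneList",
    "NnaModel",
    "CvCurve",
    "task_labels",
    "split_cohort",
    "relieff_rank",
    "fit_nna",
    "nna_predict",
    "cross_validate_topk",
    "evaluate",
]


@dataclass
class RankedGeneList:
    """Genes ordered by decreasing importance weight."""

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must align")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


@dataclass
class NnaModel:
    """1-NN reference set restricted to the selected gene panel."""

    selected_genes: list[str]
    reference: np.ndarray       # n_train x k, rows are training samples
    reference_labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.selected_genes) < 1:
            raise ValueError("model needs at least one gene")
        self.reference = np.asarray(self.reference, dtype=float)
        self.reference_labels = np.asarray(self.reference_labels, dtype=int)
        if self.reference.shape != (len(self.reference_labels), len(self.selected_genes)):
            raise ValueError("reference matrix shape does not match genes/labels")


@dataclass
class CvCurve:
    """Mean CV accuracy of the nested top-k models; ``best_k`` is the argmax
    (smallest k on ties)."""

    k_values: list[int]
    mean_accuracy: np.ndarray
    best_k: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.mean_accuracy, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0,1]")
        if self.best_k not in self.k_values:
            raise ValueError("best_k outside k_values")


def task_labels(matrix: ExpressionMatrix, task: str,
                age_threshold: float = 50.0) -> np.ndarray:
    """0/1 labels for a task. ``aging``: 1 iff age > threshold (50 y default);
    ``disease``: 1 iff diagnosis is AD."""
    if task == "aging":
        return (matrix.samples["age"].to_numpy(float) > age_threshold).astype(int)
    if task == "disease":
        return (matrix.samples["diagnosis"].to_numpy() == "AD").astype(int)
    raise ValueError(f"unknown task '{task}' (expected 'aging' or 'disease')")


def split_cohort(matrix: ExpressionMatrix, task: str, seed: int,
                 age_threshold: float = 50.0,
                 train_fraction: float = 2 / 3) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified random 2:1 train/test split for a task.

    Each label stratum is split ``train_fraction`` : rest independently, so
    class proportions in the two parts match as closely as the counts allow.
    A class with fewer than 3 samples cannot be split 2:1 and raises.
    """
    labels = task_labels(matrix, task, age_threshold)
    rng = np.random.default_rng(seed)
    ids = np.array(matrix.sample_ids)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in np.unique(labels):
        pos = np.flatnonzero(labels == cls)
        if len(pos) < 3:
            raise ValueError(f"class {cls} has only {len(pos)} samples; cannot split 2:1")
        perm = rng.permutation(pos)
        n_train = int(round(len(pos) * train_fraction))
        n_train = min(max(n_train, 1), len(pos) - 1)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    # preserve the cohort's sample order inside each part
    order = {s: i for i, s in enumerate(ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return matrix.subset_samples(train_ids), matrix.subset_samples(test_ids)


def relieff_rank(matrix: ExpressionMatrix, labels: np.ndarray,
                 k_neighbors: int = 10) -> RankedGeneList:
    """ReliefF gene weights for a binary task, genes sorted by weight.

    Every training sample is visited once (m = n).  Features are
    range-normalized; per-feature difference is the absolute difference of
    normalized values, and neighbourhoods are the ``k_neighbors`` nearest
    samples under the Manhattan distance on those normalized features.  The
    weight of a gene is the mean difference to nearest misses minus the mean
    difference to nearest hits, averaged over all visits.  Constant genes get
    weight 0.
    """
    labels = np.asarray(labels, dtype=int)
    X = matrix.values.to_numpy(float).T  # samples x genes
    n, g = X.shape
    if len(labels) != n:
        raise ValueError("labels do not match sample count")
    if not np.isfinite(X).all():
        raise ValueError("ReliefF requires finite expression values")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ReliefF here supports binary labels only")

    span = X.max(axis=0) - X.min(axis=0)
    constant = span == 0.0
    span = np.where(constant, 1.0, span)
    Z = X / span
    Z[:, constant] = 0.0  # constant features contribute no difference

    weights = np.zeros(g)
    # pairwise Manhattan distances on normalized features (n <= a few hundred)
    dist = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2) if n * n * g <= 5_000_000 \
        else _pairwise_manhattan_blocked(Z)
    np.fill_diagonal(dist, np.inf)

    for i in range(n):
        same = labels == labels[i]
        hits = np.flatnonzero(same)
        hits = hits[hits != i]
        misses = np.flatnonzero(~same)
        kh = min(k_neighbors, len(hits))
        km = min(k_neighbors, len(misses))
        if kh == 0 or km == 0:
            raise ValueError("each class needs at least 2 samples for ReliefF")
        nh = hits[np.argsort(dist[i, hits], kind="stable")[:kh]]
        nm = misses[np.argsort(dist[i, misses], kind="stable")[:km]]
        weights += np.abs(Z[nm] - Z[i]).mean(axis=0) - np.abs(Z[nh] - Z[i]).mean(axis=0)
    weights /= n

    genes = np.array(matrix.genes)
    # deterministic: sort by weight desc, symbol asc on ties
    order = np.lexsort((genes, -weights))
    return RankedGeneList(genes=list(genes[order]), weights=weights[order])


def _pairwise_manhattan_blocked(Z: np.ndarray, block: int = 64) -> np.ndarray:
    n = Z.shape[0]
    out = np.empty((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = np.abs(Z[start:stop, None, :] - Z[None, :, :]).sum(axis=2)
    return out


def fit_nna(train: ExpressionMatrix, labels: np.ndarray,
            selected_genes: list[str]) -> NnaModel:
    """Store the training samples restricted to the selected panel."""
    ref = train.values.loc[selected_genes].to_numpy(float).T
    return NnaModel(selected_genes=list(selected_genes), reference=ref,
                    reference_labels=np.asarray(labels, dtype=int))


def _cosine_distances(A: np.ndarray, B: np.ndarray,
                      names: list[str] | None = None) -> np.ndarray:
    """1 - cosine similarity between rows of A (queries) and rows of B."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if (na == 0).any():
        bad = [names[i] if names else str(i) for i in np.flatnonzero(na == 0)]
        raise ValueError(f"zero-norm sample vector(s): {bad[:5]}")
    if (nb == 0).any():
        raise ValueError("zero-norm reference vector(s)")
    return 1.0 - (A @ B.T) / np.outer(na, nb)


def nna_predict(model: NnaModel,
                query: ExpressionMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and margin scores for query samples.

    For each query, ``d0``/``d1`` are the one-minus-cosine distances to the
    nearest label-0/label-1 reference; the prediction is 1 iff ``d1 < d0``
    (ties go to 0) and the continuous score is ``d0 - d1`` (larger = more
    class-1, used for ROC curves).
    """
    if isinstance(query, ExpressionMatrix):
        Q = query.values.loc[model.selected_genes].to_numpy(float).T
        names = query.sample_ids
    else:
        Q = np.asarray(query, dtype=float)
        names = None
    dist = _cosine_distances(Q, model.reference, names)
    mask1 = model.reference_labels == 1
    if not mask1.any() or mask1.all():
        raise ValueError("reference set must contain both classes")
    d0 = dist[:, ~mask1].min(axis=1)
    d1 = dist[:, mask1].min(axis=1)
    scores = d0 - d1
    labels = (d1 < d0).astype(int)
    return labels, scores


def cross_validate_topk(train: ExpressionMatrix, labels: np.ndarray,
                        ranking: RankedGeneList, top_models: int = 100,
                        folds: int = 5, seed: int = 0) -> CvCurve:
    """Stratified k-fold CV accuracy of the nested top-k gene models.

    Evaluates k = 1..``top_models`` (clipped to the gene count with a
    warning) and returns the accuracy curve with ``best_k`` the smallest
    maximizer.  Cosine distances for nested panels are updated incrementally
    as genes are appended, so the scan over k costs one rank-1 update per
    gene per fold.
    """
    labels = np.asarray(labels, dtype=int)
    n = train.n_samples
    if top_models > train.n_genes:
        warnings.warn(f"top_models={top_models} clipped to {train.n_genes} genes")
        top_models = train.n_genes
    X = train.values.loc[ranking.genes[:top_models]].to_numpy(float).T  # n x K

    if folds >= n:
        splitter = LeaveOneOut()
        splits = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, labels)

    correct = np.zeros(top_models)
    for tr_idx, te_idx in splits:
        correct += _fold_topk_correct(X[tr_idx], labels[tr_idx], X[te_idx], labels[te_idx])
    acc = correct / n
    best_k = int(np.argmax(acc)) + 1  # argmax returns the first (smallest) maximizer
    return CvCurve(k_values=list(range(1, top_models + 1)), mean_accuracy=acc,
                   best_k=best_k)


def _fold_topk_correct(Xtr: np.ndarray, ytr: np.ndarray,
                       Xte: np.ndarray, yte: np.ndarray) -> np.ndarray:
    """Correct-prediction counts per nested panel size for one fold."""
    K = Xtr.shape[1]
    dots = np.zeros((Xte.shape[0], Xtr.shape[0]))
    sq_tr = np.zeros(Xtr.shape[0])
    sq_te = np.zeros(Xte.shape[0])
    mask1 = ytr == 1
    correct = np.zeros(K)
    for k in range(K):
        dots += np.outer(Xte[:, k], Xtr[:, k])
        sq_tr += Xtr[:, k] ** 2
        sq_te += Xte[:, k] ** 2
        norm = np.outer(np.sqrt(sq_te), np.sqrt(sq_tr))
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - dots / norm
        dist = np.where(np.isfinite(dist), dist, 1.0)  # zero-norm prefix: no information
        d0 = dist[:, ~mask1].min(axis=1)
        d1 = dist[:, mask1].min(axis=1)
        pred = (d1 < d0).astype(int)
        correct[k] = (pred == yte).sum()
    return correct


def auc_from_scores(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the trapezoid rule over the score-thresholded ROC curve.

    Equals the Mann-Whitney concordance of the scores (ties count half).
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr))


def evaluate(model: NnaModel, test: ExpressionMatrix,
             test_labels: np.ndarray) -> dict:
    """Held-out AUC (trapezoid over the score ROC), accuracy, and ROC points."""
    test_labels = np.asarray(test_labels, dtype=int)
    if len(np.unique(test_labels)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    pred, scores = nna_predict(model, test)
    fpr, tpr, _ = roc_curve(test_labels, scores)
    return {
        "auc": auc_from_scores(test_labels, scores),
        "accuracy": float((pred == test_labels).mean()),
        "roc_points": np.column_stack([fpr, tpr]),
    }
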