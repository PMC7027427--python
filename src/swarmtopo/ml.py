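"""Parameter recovery and phenotype classification from feature vectors.

Unsupervised route: PAM k-medoids (deterministic BUILD initialization +
SWAP refinement under Euclidean distance) with k = 25, one cluster per
generating (C, ell) combination. Supervised route: one-vs-one linear SVM
with stratified 5-fold cross-validation. Either way a simulation counts as
correctly recovered when its predicted (C, ell) class matches the one that
generated it; phenotype accuracy follows by collapsing parameter classes
through the phenotype map, so supervised phenotype accuracy can never fall
below parameter accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .model import PARAM_GRID, PHENOTYPE_MAP, PHENOTYPES

__all__ = [
    "EvaluationReport",
    "pca_reduce",
    "kmedoids_cluster",
    "cluster_accuracy",
    "svm_train_eval",
    "run_benchmark",
    "phenotype_index_of_label",
]


def phenotype_index_of_label() -> np.ndarray:
    """Map from (C, ell) class index (into PARAM_GRID) to phenotype index."""
    lut = {p: i for i, p in enumerate(PHENOTYPES)}
    return np.array([lut[PHENOTYPE_MAP[combo]] for combo in PARAM_GRID],
                    dtype=np.intp)


@dataclass
class EvaluationReport:
    """Accuracies and confusion matrices of one classification experiment."""

    parameter_accuracy: float
    phenotype_accuracy: float
    param_confusion: np.ndarray  # (n_classes, n_classes), rows = truth
    pheno_confusion: np.ndarray  # (7, 7), rows = truth
    method: dict = field(default_factory=dict)


def pca_reduce(features: np.ndarray, target_dim: int) -> np.ndarray:
    """Mean-centered projection onto the top principal components.

    Fit on the full matrix (the train-only alternative lives inside
    svm_train_eval behind ``pca_scope='train'``).
    """
    x = np.asarray(features, dtype=float)
    if target_dim > min(x.shape):
        raise ValueError("target_dim exceeds the feature matrix rank bound")
    return PCA(n_components=target_dim, svd_solver="auto",
               random_state=0).fit_transform(x)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    first = int(np.argmin(D.sum(axis=0)))
    medoids = [first]
    nearest = D[:, first].copy()
    for _ in range(k - 1):
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))  # ties -> lowest index
        medoids.append(h)
        nearest = np.minimum(nearest, D[:, h])
    return medoids


def kmedoids_cluster(features: np.ndarray, k: int = 25,
                     max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """PAM clustering: greedy BUILD then best-improvement SWAP until no swap
    lowers the total within-cluster distance to medoids.

    Deterministic (no randomness): BUILD is greedy and ties break toward the
    lowest index. Returns (assignments, medoid_indices).
    """
    x = np.asarray(features, dtype=float)
    n = len(x)
    if k > n:
        raise ValueError("k cannot exceed the number of rows")
    D = cdist(x, x)
    medoids = _pam_build(D, k)

    for _ in range(max_iter):
        Dm = D[:, medoids]  # (n, k)
        order = np.argsort(Dm, axis=1, kind="stable")
        n1 = order[:, 0]
        d1 = Dm[np.arange(n), n1]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        total = d1.sum()

        best_delta = -1e-9
        best = None
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        for mi in range(k):
            e = np.where(n1 == mi, d2, d1)
            cost_h = np.minimum(D, e[:, None]).sum(axis=0) - total
            cost_h[in_medoids] = np.inf
            h = int(np.argmin(cost_h))
            if cost_h[h] < best_delta:
                best_delta = float(cost_h[h])
                best = (mi, h)
        if best is None:
            break
        medoids[best[0]] = best[1]

    medoids_arr = np.array(medoids)
    assignments = np.argmin(D[:, medoids_arr], axis=1)
    return assignments, medoids_arr


def _majority_map(assignments: np.ndarray, truth: np.ndarray,
                  n_clusters: int, n_classes: int) -> np.ndarray:
    """Cluster -> most frequent true class; ties -> lowest class index;
    empty clusters -> -1 (members scored incorrect)."""
    mapping = np.full(n_clusters, -1, dtype=np.intp)
    for c in range(n_clusters):
        members = truth[assignments == c]
        if len(members):
            counts = np.bincount(members, minlength=n_classes)
            mapping[c] = int(np.argmax(counts))
    return mapping


def _hungarian_map(assignments: np.ndarray, truth: np.ndarray,
                   n_clusters: int, n_classes: int) -> np.ndarray:
    overlap = np.zeros((n_clusters, n_classes))
    for c, t in zip(assignments, truth):
        overlap[c, t] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = np.full(n_clusters, -1, dtype=np.intp)
    mapping[rows] = cols
    return mapping


def _confusion(truth: np.ndarray, pred: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n), dtype=np.int64)
    valid = pred >= 0
    np.add.at(m, (truth[valid], pred[valid]), 1)
    # predictions of -1 (empty-cluster members) are counted as errors but
    # appear in no predicted column
    return m


def cluster_accuracy(assignments: np.ndarray, label_indices: np.ndarray,
                     phenotype_indices: np.ndarray,
                     n_classes: int = 25,
                     mapping: str = "majority") -> EvaluationReport:
    """Score a clustering against the generating labels.

    Each cluster is mapped to a (C, ell) class — majority vote by default,
    optionally one-to-one Hungarian assignment — and independently to a
    majority phenotype; accuracies are the fractions of simulations whose
    cluster's label matches their own.
    """
    assignments = np.asarray(assignments)
    truth = np.asarray(label_indices)
    ptruth = np.asarray(phenotype_indices)
    n_clusters = int(assignments.max()) + 1 if len(assignments) else 0
    mapper = {"majority": _majority_map, "hungarian": _hungarian_map}[mapping]
    cmap = mapper(assignments, truth, n_clusters, n_classes)
    pmap = _majority_map(assignments, ptruth, n_clusters, len(PHENOTYPES))
    pred = cmap[assignments]
    ppred = pmap[assignments]
    return EvaluationReport(
        parameter_accuracy=float(np.mean(pred == truth)),
        phenotype_accuracy=float(np.mean(ppred == ptruth)),
        param_confusion=_confusion(truth, pred, n_classes),
        pheno_confusion=_confusion(ptruth, ppred, len(PHENOTYPES)),
        method={"algorithm": "kmedoids", "k": n_clusters, "mapping": mapping},
    )


def svm_train_eval(features: np.ndarray, label_indices: np.ndarray,
                   phenotype_indices: np.ndarray | None = None,
                   folds: int = 5, seed: int = 0,
                   pca_dim: int | None = None,
                   pca_scope: str = "full",
                   n_classes: int = 25) -> EvaluationReport:
    """One-vs-one linear SVM under stratified k-fold cross-validation.

    C = 1, hinge loss, no feature standardization. ``pca_dim`` optionally
    reduces dimensionality first; with the default scope the projection is
    fit on the full matrix before splitting (which leaks fold information —
    kept as the primary convention for comparability, with 'train' fitting
    per fold as the clean alternative). Accuracy is the mean out-of-sample
    fraction over folds; confusion matrices pool all held-out predictions.
    Phenotype accuracy maps predicted parameter classes through the
    phenotype table.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(label_indices)
    counts = np.bincount(y)
    if counts[counts > 0].min() < folds:
        raise ValueError(f"every class needs at least {folds} members "
                         "for stratified cross-validation")
    if phenotype_indices is None:
        phenotype_indices = phenotype_index_of_label()[y]
    ptruth = np.asarray(phenotype_indices)
    label_to_pheno = phenotype_index_of_label()

    if pca_dim is not None and pca_scope == "full":
        x = pca_reduce(x, pca_dim)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    pred_all = np.empty(len(y), dtype=np.intp)
    for train, test in skf.split(x, y):
        xtr, xte = x[train], x[test]
        if pca_dim is not None and pca_scope == "train":
            p = PCA(n_components=pca_dim, random_state=0).fit(xtr)
            xtr, xte = p.transform(xtr), p.transform(xte)
        clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovo")
        clf.fit(xtr, y[train])
        pred = clf.predict(xte)
        pred_all[test] = pred
        fold_acc.append(float(np.mean(pred == y[test])))

    ppred = label_to_pheno[pred_all]
    return EvaluationReport(
        parameter_accuracy=float(np.mean(fold_acc)),
        phenotype_accuracy=float(np.mean(ppred == ptruth)),
        param_confusion=_confusion(y, pred_all, n_classes),
        pheno_confusion=_confusion(ptruth, ppred, len(PHENOTYPES)),
        method={"algorithm": "svm", "folds": folds, "seed": seed,
                "pca_dim": pca_dim, "pca_scope": pca_scope},
    )


def run_benchmark(feature_matrices: dict, label_indices: np.ndarray,
                  phenotype_indices: np.ndarray,
                  methods: tuple = ("kmedoids", "svm"),
                  pca_dims: tuple = (None,),
                  k: int = 25, folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """One evaluation per (feature set, method, PCA dimension) cell.

    ``feature_matrices`` maps "summary/feature" names (e.g. "op/D_NN",
    "tda_delay/b0") to row-per-simulation matrices. Returns a tidy frame
    with parameter and phenotype accuracies in percent; infeasible cells
    (e.g. PCA dimension above the matrix rank) are skipped.
    """
    rows = []
    for name, x in feature_matrices.items():
        for method in methods:
            dims = pca_dims if method == "svm" else (None,)
            for dim in dims:
                if dim is not None and dim > min(np.asarray(x).shape):
                    continue
                if method == "kmedoids":
                    xr = np.asarray(x, dtype=float)
                    assign, _ = kmedoids_cluster(xr, k=k)
                    rep = cluster_accuracy(assign, label_indices,
                                           phenotype_indices)
                else:
                    rep = svm_train_eval(x, label_indices, phenotype_indices,
                                         folds=folds, seed=seed, pca_dim=dim)
                rows.append({
                    "feature": name,
                    "method": method,
                    "dimension": (dim if dim is not None
                                  else int(np.asarray(x).shape[1])),
                    "parameter_pct": 100.0 * rep.parameter_accuracy,
                    "phenotype_pct": 100.0 * rep.phenotype_accuracy,
                })
    return pd.DataFrame(rows)
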