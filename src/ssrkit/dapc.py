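"""Non-model-based structure inference: allele-count coding, PCA,
sequential K-means with BIC model selection, discriminant analysis of
principal components, and a-score PC retention."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ClusterSearch",
    "DAPCResult",
    "allele_count_coding",
    "find_clusters",
    "dapc_fit",
    "a_score_optimize",
]


def allele_count_coding(G: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Individuals x (locus, allele) matrix of 0/1/2 allele copies.

    Missing calls are imputed with the column mean; columns are
    mean-centered; monomorphic columns are dropped.  Returns the matrix
    and the (locus, allele) column labels.
    """
    cols: list[np.ndarray] = []
    labels: list[tuple[str, int]] = []
    missing = G.missing_mask()
    for l, locus in enumerate(G.loci):
        calls = G.calls[:, l, :]
        alleles = np.unique(calls[calls != MISSING])
        for allele in alleles:
            col = (calls == allele).sum(axis=1).astype(float)
            miss = missing[:, l]
            if miss.all():
                continue
            mean = col[~miss].mean()
            col[miss] = mean
            if np.allclose(col, col[0]):
                continue  # monomorphic after imputation
            cols.append(col - col.mean())
            labels.append((locus, int(allele)))
    if not cols:
        raise ValueError("no polymorphic columns")
    return np.column_stack(cols), labels


@dataclass
class ClusterSearch:
    bic_curve: dict[int, float]
    best_k: int
    assignments: np.ndarray
    weak: bool
    n_pc: int
    seed: int | None


def _pca_reduce(X: np.ndarray, n_pc: int | float | None) -> np.ndarray:
    """PCA scores; ``n_pc`` may be a count, a variance fraction, or None
    (keep 95% variance)."""
    max_pc = min(X.shape[0] - 1, X.shape[1])
    if n_pc is None:
        n_pc = 0.95
    if isinstance(n_pc, float) and 0 < n_pc < 1:
        pca = PCA(n_components=min(max_pc, X.shape[1]), svd_solver="full")
        scores = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, n_pc) + 1)
        return scores[:, :keep]
    n_pc = min(int(n_pc), max_pc)
    return PCA(n_components=n_pc, svd_solver="full").fit_transform(X)


def find_clusters(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 21),
    n_pc_prefilter: int | float | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
) -> ClusterSearch:
    """Sequential K-means over ``k_range`` with BIC model selection.

    BIC(K) = n * ln(WSS_K / n) + K * ln(n); the best K minimizes the
    curve.  The result is flagged ``weak`` when the best K improves on
    K=min(k_range) by less than one BIC unit.
    """
    scores = _pca_reduce(X, n_pc_prefilter)
    n = scores.shape[0]
    rng = np.random.default_rng(seed)
    bic: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > n:
            continue
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(scores)
        wss = float(km.inertia_)
        bic[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        assignments[k] = km.labels_
    best_k = min(bic, key=lambda k: (bic[k], k))
    # decrease achieved relative to the smallest K scanned
    weak = (bic[min(bic)] - bic[best_k]) < 1.0
    return ClusterSearch(
        bic_curve=bic,
        best_k=best_k,
        assignments=assignments[best_k],
        weak=weak,
        n_pc=scores.shape[1],
        seed=seed,
    )


@dataclass
class DAPCResult:
    k: int
    n_pc_retained: int
    coordinates: np.ndarray  # individuals x discriminant axes
    membership: np.ndarray  # individuals x clusters, rows sum to 1
    assignments: np.ndarray
    classes: np.ndarray
    seed: int | None = None
    bic_curve: dict[int, float] | None = None


def dapc_fit(
    X: np.ndarray,
    assignments: Sequence[int],
    n_pc: int,
    seed: int | None = None,
) -> DAPCResult:
    """Linear discriminant analysis on the first ``n_pc`` PCs.

    At most K-1 discriminant axes; membership probabilities are the
    Gaussian posteriors in discriminant space.  Raises when ``n_pc``
    reaches n - K (overfit guard).
    """
    y = np.asarray(assignments)
    classes = np.unique(y)
    k = len(classes)
    n = X.shape[0]
    if n_pc >= n - k:
        raise ValueError(f"n_pc={n_pc} >= n - K = {n - k}: overfitting guard")
    scores = _pca_reduce(X, n_pc)
    lda = LinearDiscriminantAnalysis(n_components=min(k - 1, scores.shape[1]))
    coords = lda.fit_transform(scores, y)
    membership = lda.predict_proba(scores)
    return DAPCResult(
        k=k,
        n_pc_retained=scores.shape[1],
        coordinates=coords,
        membership=membership,
        assignments=lda.predict(scores),
        classes=classes,
        seed=seed,
    )


def _reassignment_proportion(X_pc: np.ndarray, y: np.ndarray) -> float:
    k = len(np.unique(y))
    lda = LinearDiscriminantAnalysis(n_components=min(k - 1, X_pc.shape[1]))
    pred = lda.fit(X_pc, y).predict(X_pc)
    return float(np.mean(pred == y))


def a_score_optimize(
    X: np.ndarray,
    assignments: Sequence[int],
    n_perm: int = 10,
    seed: int | None = None,
    pc_grid: Sequence[int] | None = None,
) -> tuple[int, dict[int, float]]:
    """a-score scan over retained-PC counts; returns (optimum, curve).

    a-score(n_pc) = observed reassignment proportion minus the mean
    proportion after ``n_perm`` random permutations of the labels.
    """
    y = np.asarray(assignments)
    k = len(np.unique(y))
    n = X.shape[0]
    max_pc = min(n - k - 1, X.shape[1], n - 1)
    if pc_grid is None:
        pc_grid = range(1, max(max_pc + 1, 2))
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    full_scores = _pca_reduce(X, max_pc)
    for n_pc in pc_grid:
        if n_pc < 1 or n_pc > max_pc:
            continue
        scores = full_scores[:, :n_pc]
        obs = _reassignment_proportion(scores, y)
        null = []
        for _ in range(n_perm):
            perm = rng.permutation(y)
            null.append(_reassignment_proportion(scores, perm))
        curve[n_pc] = obs - float(np.mean(null))
    best = max(curve, key=lambda p: (curve[p], -p))
    return best, curve
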