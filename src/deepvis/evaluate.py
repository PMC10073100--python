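"""Embedding quality criteria.

Structure preservation uses the scale-independent co-ranking criteria:
from the co-ranking matrix (the joint histogram of neighbor ranks in
high- vs low-dimensional space) we form the curve

    Q_NX(K) = (1/(K·n)) · Σ_{k,l ≤ K} c_kl,

split the scales at K* = argmax_K [Q_NX(K) − K/(n−1)] and report
Q_local (mean of Q_NX up to K*) and Q_global (mean beyond K*), both in
[0, 1]. Low-dimensional distances use the embedding's own manifold
metric; high-dimensional distances are Euclidean on the model input.

Batch handling follows the per-batch protocol (score each batch's cells
separately against the uncorrected input), plus a k-NN label-transfer
accuracy with leave-one-group-out support and a normalized batch-mixing
statistic for how thoroughly batches interleave in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ManifoldSpec
from .io import EmbeddingTable

__all__ = ["CorankingMatrix", "QualityReport", "coranking",
           "quality_scores", "per_batch_quality", "knn_transfer_accuracy",
           "leave_one_group_out_accuracy", "batch_mixing"]

SUBSAMPLE_CAP = 3000  # co-ranking is O(n²) memory


@dataclass
class CorankingMatrix:
    counts: np.ndarray  # (n-1) × (n-1)

    @property
    def n(self) -> int:
        return self.counts.shape[0] + 1

    def q_nx(self) -> np.ndarray:
        """Q_NX(K) for K = 1 .. n−1."""
        n = self.n
        cum = np.cumsum(np.cumsum(self.counts, axis=0), axis=1)
        K = np.arange(1, n)
        return np.diag(cum) / (K * n)


@dataclass
class QualityReport:
    q_local: float
    q_global: float
    split_k: int
    n_used: int
    acc: float | None = None
    group: str | None = None


def _rank_matrix(D: np.ndarray) -> np.ndarray:
    """Per-row ranks of the other points (1 = nearest); self excluded,
    ties broken by the lower column index."""
    n = D.shape[0]
    D = np.asarray(D, dtype=float).copy()
    np.fill_diagonal(D, np.inf)
    order = np.lexsort((np.broadcast_to(np.arange(n), D.shape), D), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(n)[None, :] + 1  # self lands at rank n
    return ranks


def _pairwise(Z: np.ndarray, spec: ManifoldSpec | None) -> np.ndarray:
    from .geometry import pairwise_distance_matrix
    if spec is None:
        spec = ManifoldSpec("euclidean", latent_dim=Z.shape[1])
    return np.asarray(pairwise_distance_matrix(np.asarray(Z, float), spec))


def coranking(D_high: np.ndarray, D_low: np.ndarray) -> CorankingMatrix:
    """Co-occurrence counts of (high-dim rank, low-dim rank) pairs."""
    D_high, D_low = np.asarray(D_high), np.asarray(D_low)
    if D_high.shape != D_low.shape or D_high.ndim != 2:
        raise ValueError("distance matrices must share a square shape")
    n = D_high.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    Rh = _rank_matrix(D_high)
    Rl = _rank_matrix(D_low)
    off = ~np.eye(n, dtype=bool)
    counts = np.zeros((n - 1, n - 1), dtype=np.int64)
    np.add.at(counts, (Rh[off] - 1, Rl[off] - 1), 1)
    return CorankingMatrix(counts)


def _split_scores(q: np.ndarray, n: int):
    K = np.arange(1, n)
    lcmc = q - K / (n - 1)
    split = int(np.argmax(lcmc)) + 1
    q_local = float(np.mean(q[:split]))
    q_global = float(np.mean(q[split:])) if split < n - 1 else float(q[-1])
    return q_local, q_global, split


def quality_scores(X_high, Z_low, manifold: ManifoldSpec | None = None,
                   cap: int = SUBSAMPLE_CAP, seed: int = 0) -> QualityReport:
    """Q_local / Q_global between input space and embedding.

    ``Z_low`` may be an :class:`EmbeddingTable` (its manifold metric is
    used) or a plain array (Euclidean unless ``manifold`` is given).
    Above ``cap`` cells, a seeded subsample keeps co-ranking tractable.
    """
    if isinstance(Z_low, EmbeddingTable):
        manifold = Z_low.manifold
        Z_low = Z_low.coords
    X_high = np.asarray(X_high, dtype=float)
    Z_low = np.asarray(Z_low, dtype=float)
    if X_high.shape[0] != Z_low.shape[0]:
        raise ValueError("row mismatch between input and embedding")
    n = X_high.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells for a meaningful curve")
    if n > cap:
        keep = np.random.default_rng(seed).choice(n, cap, replace=False)
        X_high, Z_low = X_high[keep], Z_low[keep]
        n = cap
    D_high = _pairwise(X_high, None)
    D_low = _pairwise(Z_low, manifold)
    q = coranking(D_high, D_low).q_nx()
    q_local, q_global, split = _split_scores(q, n)
    return QualityReport(q_local, q_global, split, n)


def per_batch_quality(X_high, Z_low, batch_labels,
                      manifold: ManifoldSpec | None = None,
                      min_cells: int = 10, seed: int = 0):
    """Quality scores within each batch's cells (uncorrected input vs
    final embedding); batches below ``min_cells`` are skipped with a
    placeholder entry."""
    if isinstance(Z_low, EmbeddingTable):
        manifold = Z_low.manifold
        Z_low = Z_low.coords
    X_high = np.asarray(X_high, dtype=float)
    Z_low = np.asarray(Z_low, dtype=float)
    batch_labels = np.asarray(batch_labels)
    reports = []
    usable = 0
    for lev in np.unique(batch_labels):
        mask = batch_labels == lev
        if mask.sum() < min_cells:
            reports.append(QualityReport(np.nan, np.nan, 0, int(mask.sum()),
                                         group=str(lev)))
            continue
        r = quality_scores(X_high[mask], Z_low[mask], manifold, seed=seed)
        r.group = str(lev)
        reports.append(r)
        usable += 1
    if usable == 0:
        raise ValueError("every batch has fewer cells than min_cells")
    return reports


def _cross_distances(A: np.ndarray, B: np.ndarray,
                     spec: ManifoldSpec | None) -> np.ndarray:
    A, B = np.asarray(A, float), np.asarray(B, float)
    if spec is None or spec.kind == "euclidean":
        d2 = np.maximum(np.sum(A * A, 1)[:, None] + np.sum(B * B, 1)[None, :]
                        - 2 * A @ B.T, 0.0)
        return np.sqrt(d2)
    from .geometry import poincare_distance, lorentz_distance
    if spec.kind == "poincare":
        return poincare_distance(A[:, None, :], B[None, :, :], spec.curvature)
    return lorentz_distance(A[:, None, :], B[None, :, :], spec.curvature)


def knn_transfer_accuracy(Z_train, labels_train, Z_test, labels_test,
                          k: int = 5, manifold: ManifoldSpec | None = None,
                          ignore_unseen: bool = False) -> float:
    """Majority-vote k-NN accuracy under the manifold metric.

    Vote ties are broken by the smallest mean distance among the tied
    labels. Test labels absent from training count as errors unless
    ``ignore_unseen`` drops those cells.
    """
    labels_train = np.asarray(labels_train)
    labels_test = np.asarray(labels_test)
    if labels_train.size == 0 or labels_test.size == 0:
        raise ValueError("labels must be nonempty")
    if k > labels_train.size:
        raise ValueError("k exceeds the number of training cells")
    if isinstance(Z_train, EmbeddingTable):
        manifold = Z_train.manifold
        Z_train = Z_train.coords
    if isinstance(Z_test, EmbeddingTable):
        Z_test = Z_test.coords
    if ignore_unseen:
        seen = np.isin(labels_test, labels_train)
        if not np.any(seen):
            raise ValueError("no test cell has a training label")
        Z_test = np.asarray(Z_test)[seen]
        labels_test = labels_test[seen]
    D = _cross_distances(Z_test, Z_train, manifold)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    correct = 0
    for i in range(D.shape[0]):
        votes = labels_train[nn[i]]
        dists = D[i, nn[i]]
        uniq, counts = np.unique(votes, return_counts=True)
        top = uniq[counts == counts.max()]
        if top.size == 1:
            pred = top[0]
        else:
            means = [dists[votes == u].mean() for u in top]
            pred = top[int(np.argmin(means))]
        correct += pred == labels_test[i]
    return correct / D.shape[0]


def leave_one_group_out_accuracy(Z, labels, groups, k: int = 5,
                                 manifold: ManifoldSpec | None = None) -> dict:
    """Per-group k-NN accuracy, training on all other groups."""
    if isinstance(Z, EmbeddingTable):
        manifold = Z.manifold
        Z = Z.coords
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        te = groups == g
        tr = ~te
        if tr.sum() < k:
            continue
        out[str(g)] = knn_transfer_accuracy(
            Z[tr], labels[tr], Z[te], labels[te], k=k, manifold=manifold)
    if not out:
        raise ValueError("no group leaves enough training cells")
    return out


def batch_mixing(Z, batch_labels, k: int = 10,
                 manifold: ManifoldSpec | None = None) -> float:
    """Normalized cross-batch neighbor fraction.

    For each cell, the fraction of its k nearest neighbors from a
    different batch, divided by the expectation under perfect mixing
    ((n − n_batch)/(n − 1)); the mean over cells is ≈ 1 for ideally
    mixed batches and → 0 for fully separated ones.
    """
    if isinstance(Z, EmbeddingTable):
        manifold = Z.manifold
        Z = Z.coords
    Z = np.asarray(Z, float)
    batch_labels = np.asarray(batch_labels)
    n = Z.shape[0]
    levels, inv = np.unique(batch_labels, return_inverse=True)
    if levels.size < 2:
        raise ValueError("batch_mixing needs at least 2 batches")
    D = _cross_distances(Z, Z, manifold)
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    other = inv[nn] != inv[:, None]
    sizes = np.bincount(inv)
    expected = (n - sizes[inv]) / (n - 1)
    return float(np.mean(other.mean(axis=1) / expected))
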