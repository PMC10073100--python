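"""kNN input graph and mixup-style interpolation augmentation.

Training batches are the sampled cells plus, for each of them, ``a``
interpolated cells: x̂ = (1−r)·x + r·x_j with x_j drawn uniformly from
the cell's k nearest input-space neighbors and r ~ U(0, p_u). The batch
encoding y is interpolated with the same r, which is what lets augmented
cells carry fractional batch membership into the batch-effect graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborGraph", "AugmentedBatch", "build_knn_graph",
           "mixup_augment"]


@dataclass
class NeighborGraph:
    k: int
    neighbor_indices: np.ndarray  # n × k, no self-neighbors
    built_on: str = "pca"

    def __post_init__(self):
        idx = np.asarray(self.neighbor_indices)
        n = idx.shape[0]
        if idx.shape != (n, self.k):
            raise ValueError("neighbor_indices must be n × k")
        if np.any((idx < 0) | (idx >= n)):
            raise ValueError("neighbor index out of range")
        if np.any(idx == np.arange(n)[:, None]):
            raise ValueError("self-neighbors are not allowed")


@dataclass
class AugmentedBatch:
    """b originals followed by a·b interpolants, with provenance."""

    X_aug: np.ndarray      # (a+1)·b × d'
    Y_aug: np.ndarray      # (a+1)·b × m (real-valued after interpolation)
    pairing: np.ndarray    # row -> index (within batch) of its source cell
    partner: np.ndarray    # row -> global index of the neighbor used (-1 for originals)
    r_values: np.ndarray   # mixing ratio per row (0 for originals)

    @property
    def n_original(self) -> int:
        return int(np.sum(self.partner < 0))


def build_knn_graph(X: np.ndarray, k: int, built_on: str = "pca",
                    chunk: int = 1024) -> NeighborGraph:
    """Exact Euclidean k-nearest-neighbor graph, self excluded.

    Ties are broken deterministically by the lower cell index. Search is
    brute force in row chunks (desk-scale datasets; no approximation).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
    sq = np.sum(X * X, axis=1)
    out = np.empty((n, k), dtype=np.int64)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d2 = sq[s:e, None] + sq[None, :] - 2.0 * (X[s:e] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(s, e) - s, np.arange(s, e)] = np.inf
        # lexsort: primary key distance, secondary key index (stable)
        order = np.lexsort((np.broadcast_to(np.arange(n), d2.shape), d2),
                           axis=1)
        out[s:e] = order[:, :k]
    return NeighborGraph(k=k, neighbor_indices=out, built_on=built_on)


def mixup_augment(X: np.ndarray, Y: np.ndarray, graph: NeighborGraph,
                  batch_indices, a: int = 1, p_u: float = 1.0,
                  rng=None) -> AugmentedBatch:
    """Emit the originals of a minibatch plus ``a`` interpolants per cell."""
    if not (0.0 < p_u <= 1.0):
        raise ValueError("p_u must be in (0, 1]")
    if a < 1:
        raise ValueError("a must be >= 1")
    batch_indices = np.asarray(batch_indices, dtype=np.int64)
    b = batch_indices.size
    if b == 0:
        raise ValueError("empty minibatch")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rows_X = [X[batch_indices]]
    rows_Y = [Y[batch_indices]]
    pairing = [np.arange(b)]
    partner = [np.full(b, -1, dtype=np.int64)]
    r_all = [np.zeros(b)]
    neigh = graph.neighbor_indices
    for _ in range(a):
        j = neigh[batch_indices, rng.integers(0, graph.k, size=b)]
        r = rng.uniform(0.0, p_u, size=b)
        rows_X.append((1.0 - r[:, None]) * X[batch_indices] + r[:, None] * X[j])
        rows_Y.append((1.0 - r[:, None]) * Y[batch_indices] + r[:, None] * Y[j])
        pairing.append(np.arange(b))
        partner.append(j)
        r_all.append(r)
    return AugmentedBatch(
        X_aug=np.vstack(rows_X), Y_aug=np.vstack(rows_Y),
        pairing=np.concatenate(pairing), partner=np.concatenate(partner),
        r_values=np.concatenate(r_all))
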