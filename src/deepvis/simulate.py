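"""Synthetic scRNA-seq generator: clusters, branching trajectories and
multilevel batch effects.

Counts follow a Poisson-gamma (negative-binomial) law on exponentiated
latent gene means, with extra dropout applied to reach a target zero
fraction — emulating the sparsity regime of droplet-based UMI data.
Two latent layouts are provided: well-separated Gaussian clusters
(discrete cell types at one time point) and a rooted branching tree
(developmental trajectories with a known normalized depth per cell).
Batch effects add per-level per-gene offsets and multiplicative jitter
to the latent log-rates before counts are drawn, forming an independent
crossed design over any number of categorical factors.

Every dataset is fully reproducible from its parameters and seed, and
keeps its latent ground truth (coordinates, labels, depth, log-rates)
for downstream evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BatchDesign, ExpressionMatrix

__all__ = ["SyntheticDataset", "make_clusters", "make_tree_trajectory",
           "inject_batch_effects"]

_LATENT_DIM = 10
_NB_SHAPE = 2.0          # gamma shape: smaller = more overdispersion
_MEAN_LIBRARY = 250.0    # mean UMIs per cell; with the heavy-tailed gene
_LIBRARY_SIGMA = 0.3     # abundances below this yields ≈60% zeros naturally,
_EXPR_SCALE = 1.0        # so default-sparsity zeros are biological, not dropout
_GENE_OFFSET_STD = 1.0   # lognormal spread of baseline gene abundance


@dataclass
class SyntheticDataset:
    X: ExpressionMatrix
    batch: BatchDesign
    cluster_labels: np.ndarray | None = None
    branch_labels: np.ndarray | None = None
    depth: np.ndarray | None = None           # normalized pseudotime in [0,1]
    latent: np.ndarray | None = None          # ground-truth latent coords
    log_rate: np.ndarray | None = None        # per-cell per-gene log mean
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.X.n_cells


def _sample_counts(log_rate: np.ndarray, sparsity: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Counts from a relative profile × independent library size.

    The latent log-rates define each cell's relative expression profile
    (softmax over genes); the per-cell total is an independent lognormal
    library size, as in droplet data where sequencing depth is technical.
    Counts are Poisson-gamma (negative binomial) around profile × depth,
    then dropout raises the zero fraction to the target (zeros are only
    added, never removed)."""
    profile = np.exp(log_rate - log_rate.max(axis=1, keepdims=True))
    profile /= profile.sum(axis=1, keepdims=True)
    lib = _MEAN_LIBRARY * rng.lognormal(
        -0.5 * _LIBRARY_SIGMA ** 2, _LIBRARY_SIGMA, size=(log_rate.shape[0], 1))
    rate = profile * lib
    lam = rate * rng.gamma(_NB_SHAPE, 1.0 / _NB_SHAPE, size=rate.shape)
    counts = rng.poisson(lam).astype(float)
    z0 = np.mean(counts == 0)
    if z0 < sparsity:
        p_drop = (sparsity - z0) / (1.0 - z0)
        counts[rng.random(counts.shape) < p_drop] = 0.0
    return counts


def _gene_lift(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Random latent → gene map; each gene loads a unit-norm direction."""
    A = rng.normal(size=(max(n_genes, _LATENT_DIM), _LATENT_DIM))
    Q, _ = np.linalg.qr(A)
    W = Q[:n_genes].T                       # latent_dim × n_genes
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    return W


def _finalize(latent, n_genes, sparsity, rng, prefix: str, params: dict,
              **labels) -> SyntheticDataset:
    n = latent.shape[0]
    W = _gene_lift(n_genes, rng)            # latent_dim × n_genes
    gene_offset = rng.normal(0.0, _GENE_OFFSET_STD, size=n_genes)
    log_rate = _EXPR_SCALE * (latent @ W) + gene_offset
    counts = _sample_counts(log_rate, sparsity, rng)
    X = ExpressionMatrix(
        counts, [f"g{j}" for j in range(n_genes)],
        [f"{prefix}{i}" for i in range(n)])
    return SyntheticDataset(
        X=X, batch=BatchDesign.single(n), latent=latent, log_rate=log_rate,
        params=params, **labels)


def make_clusters(n_cells: int = 600, n_genes: int = 200,
                  n_clusters: int = 4, separation: float = 5.0,
                  sparsity: float = 0.7, seed: int = 0) -> SyntheticDataset:
    """Discrete cell types: isotropic Gaussian clusters in latent space.

    ``separation`` scales the distance between cluster means relative to
    the unit within-cluster noise; ``sparsity`` is the target zero
    fraction of the count matrix. Zeros arise from the count law itself
    at the defaults; requesting a higher fraction adds uniform dropout
    on top (a lower fraction than the natural one cannot be honored —
    zeros are never removed).
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if not (0.0 <= sparsity < 1.0):
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_clusters, _LATENT_DIM))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    means = separation * dirs
    labels = np.repeat(np.arange(n_clusters), int(np.ceil(n_cells / n_clusters)))
    labels = rng.permutation(labels[:n_cells])  # interleave for any split
    latent = means[labels] + rng.normal(size=(n_cells, _LATENT_DIM))
    params = dict(kind="clusters", n_cells=n_cells, n_genes=n_genes,
                  n_clusters=n_clusters, separation=separation,
                  sparsity=sparsity, seed=seed)
    return _finalize(latent, n_genes, sparsity, rng, "cell", params,
                     cluster_labels=labels)


def make_tree_trajectory(depth_levels: int = 3, branching_factor: int = 2,
                         cells_per_branch: int = 86, n_genes: int = 200,
                         noise: float = 0.3, sparsity: float = 0.6,
                         seed: int = 0, step: float = 3.0) -> SyntheticDataset:
    """Branching developmental trajectory with known normalized depth.

    A rooted tree with ``depth_levels`` levels and ``branching_factor``
    children per node is laid out in latent space; each edge is a
    straight segment of length ≈ ``step`` from its parent's endpoint,
    and cells sit uniformly along edges with Gaussian noise. The depth
    of a cell is its (continuous) level divided by ``depth_levels``, so
    root-adjacent cells have depth ≈ 0 and leaf tips depth 1.
    """
    if depth_levels < 2:
        raise ValueError("need depth_levels >= 2")
    if branching_factor < 1:
        raise ValueError("branching_factor must be >= 1")
    rng = np.random.default_rng(seed)
    edges = []  # (start_point, end_point, level, branch_id)
    frontier = [np.zeros(_LATENT_DIM)]
    bid = 0
    for level in range(depth_levels):
        nxt = []
        for start in frontier:
            for _ in range(branching_factor):
                direction = rng.normal(size=_LATENT_DIM)
                direction /= np.linalg.norm(direction)
                end = start + step * direction
                edges.append((start, end, level, bid))
                bid += 1
                nxt.append(end)
        frontier = nxt
    lat_rows, depth_rows, branch_rows = [], [], []
    for start, end, level, b in edges:
        t = rng.uniform(size=cells_per_branch)
        pts = start[None, :] + t[:, None] * (end - start)[None, :]
        pts = pts + noise * rng.normal(size=pts.shape)
        lat_rows.append(pts)
        depth_rows.append((level + t) / depth_levels)
        branch_rows.append(np.full(cells_per_branch, b))
    latent = np.vstack(lat_rows)
    params = dict(kind="tree", depth_levels=depth_levels,
                  branching_factor=branching_factor,
                  cells_per_branch=cells_per_branch, n_genes=n_genes,
                  noise=noise, sparsity=sparsity, seed=seed, step=step)
    return _finalize(latent, n_genes, sparsity, rng, "cell", params,
                     branch_labels=np.concatenate(branch_rows),
                     depth=np.concatenate(depth_rows))


def inject_batch_effects(data: SyntheticDataset, factor_specs,
                         seed: int = 0) -> SyntheticDataset:
    """Overlay multilevel batch effects and resample counts.

    ``factor_specs`` is a list of ``(name, n_levels, shift_scale,
    scale_jitter)`` tuples. Levels are assigned independently per factor
    (crossed design). Each level adds a per-gene offset
    ~N(0, shift_scale) to the latent log-rates of its cells and
    multiplies rates by a per-gene log-normal jitter exp(N(0,
    scale_jitter)). With all scales 0 only the metadata changes.
    """
    if not factor_specs:
        raise ValueError("need at least one batch factor")
    rng = np.random.default_rng(seed)
    n = data.n_cells
    n_genes = data.X.n_genes
    log_rate = data.log_rate.copy()
    label_arrays = {}
    for name, n_levels, shift_scale, scale_jitter in factor_specs:
        if n_levels < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
        assign = rng.integers(0, n_levels, size=n)
        label_arrays[name] = np.array([f"{name}{a}" for a in assign])
        for lev in range(n_levels):
            mask = assign == lev
            shift = rng.normal(0.0, shift_scale, size=n_genes) \
                if shift_scale > 0 else 0.0
            jit = rng.normal(0.0, scale_jitter, size=n_genes) \
                if scale_jitter > 0 else 0.0
            log_rate[mask] = log_rate[mask] + shift + jit
    sparsity = data.params.get("sparsity", 0.6)
    counts = _sample_counts(log_rate, sparsity, rng)
    X = ExpressionMatrix(counts, list(data.X.gene_ids), list(data.X.cell_ids))
    params = dict(data.params)
    params["batch_factors"] = [tuple(map(str, fs[:1])) + tuple(fs[1:])
                               for fs in factor_specs]
    params["batch_seed"] = seed
    return SyntheticDataset(
        X=X, batch=BatchDesign.from_labels(label_arrays),
        cluster_labels=data.cluster_labels, branch_labels=data.branch_labels,
        depth=data.depth, latent=data.latent, log_rate=log_rate,
        params=params)
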