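"""The parametric embedding model: architecture, training, mapping.

The network is a six-layer fully connected stack split into a structure
module (input → 500 → 300 → 100, LeakyReLU + BN on hidden layers) and a
visualization module (100 → 300 → 100 → latent_dim). The visualization
head's raw output is interpreted as a tangent vector at the manifold
origin and pushed onto the latent manifold by the exponential map, so a
single ordinary Adam loop optimizes Euclidean and hyperbolic embeddings
alike.

Each training step: sample a minibatch, mixup-augment it along the kNN
input graph, run both modules, build the structure graph (Euclidean,
γ-contracted) and the visualization graph (manifold metric + β batch
penalty), and take a gradient step on the fuzzy cross-entropy between
them. The batch encoding never enters the network — only the loss — so
the trained encoder is batch-invariant and can map unseen batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .augment import build_knn_graph, mixup_augment, NeighborGraph
from .geometry import ManifoldSpec, lorentz_to_poincare, project_from_tangent
from .io import BatchDesign, EmbeddingTable, ExpressionMatrix
from .nn import Adam, MLP
from .preprocess import (PreprocessConfig, PreprocessModel, align_genes,
                         apply_preprocess, fit_preprocess)
from .similarity import (SimilarityConfig, gsp_loss, structure_similarity,
                         visualization_similarity)

__all__ = ["DVConfig", "DVModel", "build_model", "train", "fit",
           "transform", "save_model", "load_model"]

_ARCHIVE_VERSION = 1


@dataclass
class DVConfig:
    """Hyperparameters; defaults follow the published search-space picks:
    lr 1e-3 of {1e-3, 5e-3}, batch size 1000 of {500, 1000, 2000},
    ν^vi 5e-3 of {1e-3, 5e-3, 1e-2}, γ 1000 of {10, 1000, 1e5},
    β 1 of {1e-2, 1, 100}, ν^st 100, p_u 1, 300 epochs."""

    input_dim: int | None = None            # set from data when None
    structure_dims: tuple = (500, 300, 100)
    visualization_dims: tuple = (300, 100)
    latent_dim: int = 2
    manifold: ManifoldSpec = field(default_factory=ManifoldSpec)
    learning_rate: float = 1e-3
    batch_size: int = 1000
    epochs: int = 300
    seed: int = 0
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    k_neighbors: int = 10
    n_augment: int = 1
    p_u: float = 1.0
    last_layer_scale: float = 0.1   # keeps epoch-0 points near the origin
    dtype: str = "float64"          # training precision ("float32"/"float64")

    def __post_init__(self):
        if self.latent_dim not in (2, 3):
            raise ValueError("latent_dim must be 2 or 3")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        if self.manifold.latent_dim != self.latent_dim:
            self.manifold = ManifoldSpec(self.manifold.kind,
                                         self.manifold.curvature,
                                         self.latent_dim)

    def to_dict(self):
        d = dict(self.__dict__)
        d["structure_dims"] = list(self.structure_dims)
        d["visualization_dims"] = list(self.visualization_dims)
        d["manifold"] = self.manifold.to_dict()
        d["similarity"] = self.similarity.to_dict()
        d["preprocess"] = self.preprocess.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["structure_dims"] = tuple(d["structure_dims"])
        d["visualization_dims"] = tuple(d["visualization_dims"])
        d["manifold"] = ManifoldSpec.from_dict(d["manifold"])
        d["similarity"] = SimilarityConfig.from_dict(d["similarity"])
        d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        return cls(**d)


class DVModel:
    """Trained (or initialized) network plus its preprocessing model."""

    def __init__(self, config: DVConfig, structure_net: MLP,
                 visualization_net: MLP,
                 preprocess_model: PreprocessModel | None = None):
        self.config = config
        self.structure_net = structure_net
        self.visualization_net = visualization_net
        self.preprocess_model = preprocess_model
        self.loss_history: list[float] = []

    def parameters(self):
        return self.structure_net.parameters() + \
            self.visualization_net.parameters()

    def forward_embed(self, X_rows, training: bool = False):
        """(Z_st, Z_vi): 100-d structure embedding and on-manifold latent
        embedding. Returns tensors while training, ndarrays otherwise."""
        Xa = np.asarray(ad.asarray(X_rows), dtype=self.config.dtype)
        if Xa.ndim == 1:
            Xa = Xa[None, :]
        if Xa.shape[1] != self.config.input_dim:
            raise ValueError(f"input has {Xa.shape[1]} features, model "
                             f"expects {self.config.input_dim}")
        x = ad.Tensor(Xa) if training else Xa
        z_st = self.structure_net(x, training)
        v = self.visualization_net(z_st, training)
        z_vi = project_from_tangent(self.config.manifold, v)
        if training:
            return z_st, z_vi
        return ad.asarray(z_st), ad.asarray(z_vi)

    def embed(self, X_rows) -> np.ndarray:
        """Latent coordinates only (inference mode)."""
        return self.forward_embed(X_rows, training=False)[1]


def build_model(config: DVConfig, rng_seed: int | None = None) -> DVModel:
    """Initialize the two modules deterministically from the seed."""
    if config.input_dim is None:
        raise ValueError("config.input_dim must be set")
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    st_dims = [config.input_dim, *config.structure_dims]
    vi_dims = [config.structure_dims[-1], *config.visualization_dims,
               config.latent_dim]
    dtype = np.dtype(config.dtype).type
    structure = MLP(st_dims, rng, dtype=dtype)
    visual = MLP(vi_dims, rng, last_layer_scale=config.last_layer_scale,
                 dtype=dtype)
    return DVModel(config, structure, visual)


def train(X_input: np.ndarray, Y: BatchDesign | np.ndarray | None,
          config: DVConfig, graph: NeighborGraph | None = None,
          model: DVModel | None = None, verbose: bool = False) -> DVModel:
    """Train on preprocessed inputs (rows already at ``input_dim``).

    The batch encoding Y enters the loss only; passing ``None`` uses a
    constant encoding, which disables the batch term.
    """
    X_input = np.asarray(X_input, dtype=float)
    n = X_input.shape[0]
    if config.input_dim is None:
        config.input_dim = X_input.shape[1]
    Yenc = Y.encoding if isinstance(Y, BatchDesign) else Y
    Yenc = np.ones((n, 1)) if Yenc is None else np.asarray(Yenc, dtype=float)
    if Yenc.shape[0] != n:
        raise ValueError("batch encoding rows must match cells")
    if model is None:
        model = build_model(config)
    if graph is None:
        k = min(config.k_neighbors, n - 1)
        graph = build_knn_graph(X_input, k)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    b = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, b):
            idx = order[s:s + b]
            batch = mixup_augment(X_input, Yenc, graph, idx,
                                  a=config.n_augment, p_u=config.p_u, rng=rng)
            z_st, z_vi = model.forward_embed(batch.X_aug, training=True)
            U_st = structure_similarity(z_st, batch.pairing, config.similarity,
                                        n_original=batch.n_original)
            U_vi = visualization_similarity(z_vi, config.manifold,
                                            batch.Y_aug, config.similarity)
            loss = gsp_loss(U_st, U_vi, config.similarity)
            lval = float(ad.asarray(loss))
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, manifold="
                    f"{config.manifold.kind}); reduce the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
        model.loss_history.append(float(np.mean(losses)))
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  loss {model.loss_history[-1]:.4f}")
    return model


def fit(X: ExpressionMatrix, batch: BatchDesign | None = None,
        config: DVConfig | None = None, verbose: bool = False) -> DVModel:
    """End-to-end: fit preprocessing, build the kNN graph, train."""
    config = config or DVConfig()
    pp = fit_preprocess(X, config.preprocess)
    X_input = apply_preprocess(pp, X)
    config.input_dim = X_input.shape[1]
    model = build_model(config)
    model.preprocess_model = pp
    graph = build_knn_graph(X_input, min(config.k_neighbors, X.n_cells - 1),
                            built_on="pca" if config.preprocess.use_pca
                            else "raw")
    return train(X_input, batch, config, graph=graph, model=model,
                 verbose=verbose)


def transform(model: DVModel, X_new: ExpressionMatrix,
              return_overlap: bool = False):
    """Map new (possibly heterogeneous-gene) data with the frozen model.

    align_genes → apply_preprocess with training statistics →
    forward pass in inference mode. Nothing is refit.
    """
    if model.preprocess_model is None:
        raise ValueError("model has no attached preprocessing model")
    aligned, overlap = align_genes(model.preprocess_model.reference_genes,
                                   X_new)
    X_input = apply_preprocess(model.preprocess_model, aligned)
    coords = model.embed(X_input)
    table = EmbeddingTable(coords, model.config.manifold,
                           list(X_new.cell_ids))
    if return_overlap:
        return table, overlap / len(model.preprocess_model.reference_genes)
    return table


def poincare_view(table: EmbeddingTable) -> np.ndarray:
    """Poincaré-disk coordinates of a Lorentz embedding (for display)."""
    if table.manifold.kind != "lorentz":
        raise ValueError("poincare_view applies to Lorentz embeddings")
    return lorentz_to_poincare(table.coords, table.manifold.curvature)


# ---------------------------------------------------------------------
# archive round trip
# ---------------------------------------------------------------------

def save_model(model: DVModel, path):
    """Single-file archive: weights + BN statistics + configs + the
    preprocessing model. Portable (no paths inside)."""
    arrays = {}
    arrays.update(model.structure_net.state_arrays("st_"))
    arrays.update(model.visualization_net.state_arrays("vi_"))
    if model.preprocess_model is not None:
        arrays.update(model.preprocess_model.state_arrays())
    meta = {"version": _ARCHIVE_VERSION,
            "config": model.config.to_dict(),
            "has_preprocess": model.preprocess_model is not None,
            "loss_history": model.loss_history}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> DVModel:
    with np.load(path, allow_pickle=True) as z:
        state = {k: z[k] for k in z.files}
    meta = json.loads(str(state.pop("meta")))
    if meta.get("version") != _ARCHIVE_VERSION:
        raise ValueError(
            f"unsupported archive version {meta.get('version')!r}; "
            f"this build reads version {_ARCHIVE_VERSION}")
    config = DVConfig.from_dict(meta["config"])
    model = build_model(config)
    model.structure_net.load_state(state, "st_")
    model.visualization_net.load_state(state, "vi_")
    if meta["has_preprocess"]:
        model.preprocess_model = PreprocessModel.from_state(
            state, config.preprocess)
    model.loss_history = list(meta.get("loss_history", []))
    return model
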