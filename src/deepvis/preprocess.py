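"""Preprocessing pipeline and gene alignment for reference mapping.

Stage order: library-size normalization → log1p → per-gene
standardization → PCA (50 components). A fitted :class:`PreprocessModel`
stores every training statistic (target sum, per-gene mean/std, PCA
basis) so that query data is always transformed with training statistics
only — never refit. Heterogeneous queries are first passed through
:func:`align_genes`, which reorders shared genes, zero-fills missing
ones and drops extras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

__all__ = ["PreprocessConfig", "PreprocessModel", "fit_preprocess",
           "apply_preprocess", "align_genes"]


@dataclass
class PreprocessConfig:
    target_sum: float = 1e4
    use_normalize: bool = True
    use_log: bool = True
    use_scale: bool = True
    use_pca: bool = True
    n_pcs: int = 50

    def to_dict(self):
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class PreprocessModel:
    """Frozen training statistics for each enabled stage."""

    config: PreprocessConfig
    reference_genes: list
    gene_mean: np.ndarray | None = None
    gene_std: np.ndarray | None = None
    pca_mean: np.ndarray | None = None
    pca_components: np.ndarray | None = None  # n_pcs × d'

    @property
    def output_dim(self) -> int:
        if self.config.use_pca:
            return self.pca_components.shape[0]
        return len(self.reference_genes)

    def state_arrays(self, prefix="pp_"):
        out = {prefix + "genes": np.asarray(self.reference_genes, dtype=object)}
        for k in ("gene_mean", "gene_std", "pca_mean", "pca_components"):
            v = getattr(self, k)
            if v is not None:
                out[prefix + k] = v
        return out

    @classmethod
    def from_state(cls, state, config: PreprocessConfig, prefix="pp_"):
        if prefix + "genes" not in state:
            raise ValueError("archive is missing the preprocessing block")
        kw = {}
        for k in ("gene_mean", "gene_std", "pca_mean", "pca_components"):
            if prefix + k in state:
                kw[k] = np.asarray(state[prefix + k], dtype=float)
        return cls(config=config,
                   reference_genes=[str(g) for g in state[prefix + "genes"]],
                   **kw)


def _normalized_log(X: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    Z = np.asarray(X, dtype=float).copy()
    if cfg.use_normalize:
        rs = Z.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        Z = Z * (cfg.target_sum / rs)
    if cfg.use_log:
        Z = np.log1p(Z)
    return Z


def fit_preprocess(X: ExpressionMatrix, config: PreprocessConfig | None = None
                   ) -> PreprocessModel:
    """Fit normalization/scaling/PCA statistics on training data."""
    config = config or PreprocessConfig()
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells to fit preprocessing")
    Z = _normalized_log(X.dense(), config)
    model = PreprocessModel(config=config, reference_genes=list(X.gene_ids))
    if config.use_scale:
        model.gene_mean = Z.mean(axis=0)
        std = Z.std(axis=0)
        std[std == 0] = 1.0  # constant genes standardize to zero, not NaN
        model.gene_std = std
        Z = (Z - model.gene_mean) / model.gene_std
    if config.use_pca:
        k = min(config.n_pcs, Z.shape[0] - 1 if Z.shape[0] > 1 else 1,
                Z.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(Z)
        model.pca_mean = pca.mean_
        model.pca_components = pca.components_
    return model


def apply_preprocess(model: PreprocessModel, X) -> np.ndarray:
    """Transform (already gene-aligned) data with training statistics."""
    if isinstance(X, ExpressionMatrix):
        if X.gene_ids != model.reference_genes:
            raise ValueError("gene set not aligned; call align_genes first")
        Xv = X.dense()
    else:
        Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != len(model.reference_genes):
        raise ValueError(
            f"{Xv.shape[1]} genes, model expects {len(model.reference_genes)}")
    Z = _normalized_log(Xv, model.config)
    if model.config.use_scale:
        Z = (Z - model.gene_mean) / model.gene_std
    if model.config.use_pca:
        Z = (Z - model.pca_mean) @ model.pca_components.T
    return Z


def align_genes(reference_genes, X_query: ExpressionMatrix):
    """Project a query matrix onto the reference gene set.

    Shared genes are copied in reference order, missing genes are
    zero-filled and extra genes are dropped. Returns
    ``(aligned_matrix, overlap_count)`` and refuses a zero overlap.
    """
    reference_genes = [str(g) for g in reference_genes]
    qpos = {g: i for i, g in enumerate(X_query.gene_ids)}
    hits = [(j, qpos[g]) for j, g in enumerate(reference_genes) if g in qpos]
    if not hits:
        raise ValueError("query shares no genes with the reference")
    Q = X_query.dense()
    out = np.zeros((X_query.n_cells, len(reference_genes)))
    ref_idx, q_idx = zip(*hits)
    out[:, list(ref_idx)] = Q[:, list(q_idx)]
    aligned = ExpressionMatrix(out, list(reference_genes),
                               list(X_query.cell_ids))
    return aligned, len(hits)
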