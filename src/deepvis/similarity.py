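"""Distance → similarity graphs and the structure-preservation loss.

Edge weights of both graphs come from a normalized t-distribution
kernel g(D|ν) = C_ν · (1 + D/ν)^−(ν+1), with

    C_ν = 2π · (Γ((ν+1)/2) / (√(νπ)·Γ(ν/2)))²,

and directed similarities are merged into an undirected one by
u_ij = u_i|j + u_j|i − 2·u_i|j·u_j|i.

The structure graph uses Euclidean distances between structure-module
embeddings with cell↔own-augmentation distances contracted by γ; the
visualization graph uses the latent manifold metric with the batch
penalty β·D_E(y_i, y_j) added inside the kernel argument, which is what
drives cross-batch neighbors together in the embedding.

The loss compares the two graphs by a fuzzy-set cross entropy. Two
variants are provided: ``as_printed`` (the default; its second term
mixes the two graphs asymmetrically and the loss can be negative) and
``standard_fuzzy_ce`` (the textbook binary cross entropy between fuzzy
memberships, nonnegative, zero iff equal).

Everything here accepts either ndarrays or autodiff tensors, so the same
code evaluates the graphs numerically and differentiates them in
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import autodiff as ad
from . import _kernels as nk
from .geometry import ManifoldSpec, pairwise_distance_matrix, \
    pairwise_sq_euclidean

__all__ = ["SimilarityConfig", "normalizing_constant", "t_kernel",
           "symmetrize", "structure_similarity", "visualization_similarity",
           "gsp_loss"]

LOSS_FORMS = ("as_printed", "standard_fuzzy_ce")


@dataclass
class SimilarityConfig:
    nu_structure: float = 100.0
    nu_visualization: float = 5e-3
    gamma: float = 1000.0         # local scale contraction coefficient
    beta: float = 1.0             # batch-graph weight
    eps: float = 1e-6             # similarity clamp for the loss logs
    loss_form: str = "standard_fuzzy_ce"
    squared_input: bool = False   # feed D² to the kernel instead of D

    def __post_init__(self):
        if self.nu_structure <= 0 or self.nu_visualization <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")
        if self.loss_form not in LOSS_FORMS:
            raise ValueError(f"loss_form must be one of {LOSS_FORMS}")

    def to_dict(self):
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def normalizing_constant(nu: float) -> float:
    """C_ν, computed in log-Γ space; lies in (0, 1) and → 1 as ν → ∞."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    log_ratio = gammaln((nu + 1.0) / 2.0) - 0.5 * np.log(nu * np.pi) \
        - gammaln(nu / 2.0)
    return float(np.exp(np.log(2.0 * np.pi) + 2.0 * log_ratio))


def t_kernel(D, nu: float):
    """Directed similarity g(D|ν) = C_ν·(1 + D/ν)^−(ν+1); decreasing in D."""
    c = normalizing_constant(nu)
    return c * ad.power(1.0 + D / nu, -(nu + 1.0))


def symmetrize(u_ij, u_ji):
    """Undirected similarity u_i|j + u_j|i − 2·u_i|j·u_j|i (stays in [0,1])."""
    return u_ij + u_ji - 2.0 * u_ij * u_ji


def _kernel_input(D, cfg: SimilarityConfig):
    return D * D if cfg.squared_input else D


def _fused_gsp_terms(a, b, eps: float, form: str):
    """Clamped per-pair loss terms with closed-form gradients."""
    if not (ad.is_tensor(a) or ad.is_tensor(b)):
        raise TypeError("numpy inputs take the reference path")
    at, bt = ad._lift(a), ad._lift(b)
    ac = np.clip(at.data, eps, 1.0 - eps)
    bc = np.clip(bt.data, eps, 1.0 - eps)
    in_a = (at.data >= eps) & (at.data <= 1.0 - eps)
    in_b = (bt.data >= eps) & (bt.data <= 1.0 - eps)
    la, lb = np.log(ac), np.log(bc)
    l1a, l1b = np.log1p(-ac), np.log1p(-bc)
    if form == "standard_fuzzy_ce":
        out = ac * (la - lb) + (1.0 - ac) * (l1a - l1b)

        def grad_fn(g):
            ga = (la - lb) - (l1a - l1b)
            gb = -ac / bc + (1.0 - ac) / (1.0 - bc)
            return (g * ga * in_a, g * gb * in_b)
    else:  # as_printed
        out = ac * (la - lb) + (1.0 - bc) * (l1b - l1a)

        def grad_fn(g):
            ga = la + 1.0 - lb + (1.0 - bc) / (1.0 - ac)
            gb = -ac / bc - l1b - 1.0 + l1a
            return (g * ga * in_a, g * gb * in_b)

    return ad.Tensor(out, (at, bt), grad_fn)


def _contraction_mask(n: int, pairing, n_original: int, gamma: float,
                      dtype=np.float64) -> np.ndarray:
    """1/γ on (cell, its-own-augmentation) pairs, 1 elsewhere."""
    M = np.ones((n, n), dtype=dtype)
    pairing = np.asarray(pairing)
    for r in range(n_original, n):
        s = int(pairing[r])
        M[r, s] = M[s, r] = 1.0 / gamma
    return M


def _sq_dists_np(Z: np.ndarray) -> np.ndarray:
    n2 = np.sum(Z * Z, axis=1)
    D2 = n2[:, None] + n2[None, :] - 2.0 * (Z @ Z.T)
    return np.maximum(D2, 0.0)


def _kernel_u_forward(D, nu, c, squared):
    if nk.HAVE_NUMBA:
        return nk.kernel_graph_forward(D, nu, c, squared)
    arg = D * D if squared else D
    u = c * np.power(1.0 + arg / nu, -(nu + 1.0))
    return 2.0 * u * (1.0 - u), u


def _kernel_u_backward(g, u, D, nu, squared):
    if nk.HAVE_NUMBA:
        return nk.kernel_graph_backward(g, u, D, nu, squared)
    arg = D * D if squared else D
    gd = g * (2.0 - 4.0 * u) * (-u * ((nu + 1.0) / (nu + arg)))
    return gd * (2.0 * D) if squared else gd


def _fused_structure_graph(Z, mask, cfg: SimilarityConfig):
    """γ-contracted Euclidean kernel graph as one autodiff node.

    Forward: D = mask·√D2(Z), u = g(D or D²|ν^st), U = 2u(1−u).
    Backward reuses u and routes the D2 gradient through the standard
    squared-distance identity dL/dZ = 2(diag(S·1) − S)Z with
    S = G_D2 symmetrized — two BLAS products instead of a dozen
    broadcast temporaries.
    """
    nu = cfg.nu_structure
    c = normalizing_constant(nu)
    Zd = ad.asarray(Z)
    sq_floor = 1e-24 if Zd.dtype == np.float64 else 1e-12
    D2 = np.maximum(_sq_dists_np(Zd), sq_floor)
    D = np.sqrt(D2)
    if mask is not None:
        D = D * mask
    out, u = _kernel_u_forward(D, nu, c, cfg.squared_input)
    if not ad.is_tensor(Z):
        return out

    def grad_fn(g):
        dD = _kernel_u_backward(g, u, D, nu, cfg.squared_input)
        if mask is not None:
            dD = dD * mask
        G2 = dD / (2.0 * np.sqrt(D2))          # d√D2/dD2
        S = G2 + G2.T
        gZ = 2.0 * (S.sum(axis=1)[:, None] * Zd - S @ Zd)
        return (gZ,)

    return ad.Tensor(out, (Z,), grad_fn)


def structure_similarity(Z_st, pairing, cfg: SimilarityConfig,
                         n_original: int | None = None):
    """Similarity graph over structure embeddings (Euclidean, γ-contracted).

    ``pairing`` maps each augmented row to the batch-local index of its
    source cell; rows < ``n_original`` are the originals themselves.
    """
    n = ad.asarray(Z_st).shape[0]
    if n_original is None:
        n_original = int(np.sum(np.asarray(pairing) == np.arange(n)[:n]))
    dtype = ad.asarray(Z_st).dtype
    mask = None if cfg.gamma == 1.0 else _contraction_mask(
        n, pairing, n_original, cfg.gamma, dtype)
    return _fused_structure_graph(Z_st, mask, cfg)


def visualization_similarity(Z_vi, manifold: ManifoldSpec, Y_aug,
                             cfg: SimilarityConfig):
    """Similarity graph over latent embeddings with the batch penalty.

    The kernel argument is D_manifold(z_i, z_j) + β·D_E(y_i, y_j); with
    β = 0 (or identical batch rows) this reduces to the plain kernel of
    manifold distances.
    """
    bterm = None
    if cfg.beta > 0 and Y_aug is not None:
        Y = np.asarray(Y_aug, dtype=ad.asarray(Z_vi).dtype)
        if Y.shape[0] != ad.asarray(Z_vi).shape[0]:
            raise ValueError("Y_aug rows must match embedding rows")
        bterm = cfg.beta * np.sqrt(_sq_dists_np(Y))
    return _fused_visualization_graph(Z_vi, manifold, bterm, cfg)


def _fused_visualization_graph(Z, spec: ManifoldSpec, bterm, cfg):
    """Manifold-distance kernel graph as one autodiff node.

    Forward: D = geodesic distances of Z under ``spec`` (+ the constant
    batch penalty), u = g(D|ν^vi), U = 2u(1−u). The backward pass
    reuses the forward intermediates; the squared-distance part of each
    metric flows through dL/dZ = 2(diag(S·1) − S)Z.
    """
    from .geometry import ACOSH_EPS_GRAD, BALL_EPS
    nu = cfg.nu_visualization
    c = normalizing_constant(nu)
    K = spec.curvature
    Zd = ad.asarray(Z)
    f64 = Zd.dtype == np.float64
    sq_floor = 1e-24 if f64 else 1e-12
    acosh_floor = 1.0 + (ACOSH_EPS_GRAD if f64 else 1e-6)
    kind = spec.kind
    if kind == "euclidean":
        D2 = np.maximum(_sq_dists_np(Zd), sq_floor)
        D = np.sqrt(D2)
    elif kind == "poincare":
        n2_raw = np.sum(Zd * Zd, axis=1)
        n2_hi = (1.0 - BALL_EPS) ** 2 / K
        n2 = np.clip(n2_raw, 0.0, n2_hi)
        den = 1.0 - K * n2
        D2 = np.maximum(_sq_dists_np(Zd), 0.0)
        if nk.HAVE_NUMBA:
            A_raw, D = nk.poincare_arg_forward(D2, den, K, acosh_floor)
        else:
            A_raw = 1.0 + 2.0 * K * D2 / np.outer(den, den)
            D = np.arccosh(np.maximum(A_raw, acosh_floor)) / np.sqrt(K)
    else:  # lorentz
        signs = np.ones(Zd.shape[1], dtype=Zd.dtype)
        signs[0] = -1.0
        Zs = Zd * signs
        Gm = Zs @ Zd.T
        A_raw = -Gm / K
        D = np.sqrt(K) * np.arccosh(np.maximum(A_raw, acosh_floor))
    Dt = D + bterm if bterm is not None else D
    out, u = _kernel_u_forward(Dt, nu, c, cfg.squared_input)
    if not ad.is_tensor(Z):
        return out

    def grad_fn(g):
        gD = _kernel_u_backward(g, u, Dt, nu, cfg.squared_input)
        if kind == "euclidean":
            G2 = gD / (2.0 * D)
            S = G2 + G2.T
            return (2.0 * (S.sum(axis=1)[:, None] * Zd - S @ Zd),)
        if kind == "poincare":
            if nk.HAVE_NUMBA:
                G2, T_row, T_col = nk.poincare_arg_backward(
                    gD, A_raw, den, K, acosh_floor)
            else:
                A = np.maximum(A_raw, acosh_floor)
                gA = gD * (A_raw >= acosh_floor) / (
                    np.sqrt(K) * np.sqrt(A * A - 1.0))
                G2 = gA * (2.0 * K) / np.outer(den, den)   # dA/dD2
                T = gA * (A_raw - 1.0)
                T_row, T_col = T.sum(axis=1), T.sum(axis=0)
            S = G2 + G2.T
            gZ = 2.0 * (S.sum(axis=1)[:, None] * Zd - S @ Zd)
            gn2 = (K / den) * (T_row + T_col)
            in_ball = (n2_raw > 0.0) & (n2_raw < n2_hi)
            gZ += (2.0 * gn2 * in_ball)[:, None] * Zd
            return (gZ,)
        # lorentz
        A = np.maximum(A_raw, acosh_floor)
        gA = np.sqrt(K) * gD * (A_raw >= acosh_floor) / np.sqrt(A * A - 1.0)
        M = gA * (-1.0 / K)
        return (M.T @ Zs + (M @ Zd) * signs,)

    return ad.Tensor(out, (Z,), grad_fn)


def gsp_loss(U_st, U_vi, cfg: SimilarityConfig):
    """Geometric-structure-preservation loss between the two graphs.

    Self-pairs (the diagonal) are excluded; both matrices are clamped to
    [eps, 1−eps] before the logarithms. Returns a scalar (Tensor if
    either input is a Tensor).
    """
    if ad.asarray(U_st).shape != ad.asarray(U_vi).shape:
        raise ValueError("similarity matrices must have equal shapes")
    n = ad.asarray(U_st).shape[0]
    mask = 1.0 - np.eye(n, dtype=ad.asarray(U_st).dtype)
    if ad.is_tensor(U_st) or ad.is_tensor(U_vi):
        if nk.HAVE_NUMBA:
            at, bt = ad._lift(U_st), ad._lift(U_vi)
            total, ga, gb = nk.gsp_terms_forward(
                at.data, bt.data, cfg.eps, cfg.loss_form == "as_printed")
            return ad.Tensor(np.asarray(total), (at, bt),
                             lambda g: (g * ga, g * gb))
        return ad.tsum(_fused_gsp_terms(U_st, U_vi, cfg.eps,
                                        cfg.loss_form) * mask)
    a = np.clip(U_st, cfg.eps, 1.0 - cfg.eps)
    b = np.clip(U_vi, cfg.eps, 1.0 - cfg.eps)
    if cfg.loss_form == "standard_fuzzy_ce":
        terms = a * (np.log(a) - np.log(b)) \
            + (1.0 - a) * (np.log1p(-a) - np.log1p(-b))
    else:  # as_printed
        terms = a * (np.log(a) - np.log(b)) \
            + (1.0 - b) * (np.log1p(-b) - np.log1p(-a))
    return float(np.sum(terms * mask))
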