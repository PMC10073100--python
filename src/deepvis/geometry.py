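"""Latent-space manifolds: Euclidean space, the Poincaré ball and the
Lorentz (hyperboloid) model of hyperbolic space.

The hyperbolic models have constant negative curvature −K (K > 0). The
Poincaré ball of curvature −K is the open ball of radius 1/√K with the
conformal metric λ_x = 2 / (1 − K‖x‖²); the Lorentz model is the upper
sheet of the hyperboloid ⟨x,x⟩_L = −1, x₀ > 0 in Minkowski space. The
closed-form pieces implemented here are the geodesic distances, the
exponential maps at a point, Möbius addition for the ball, and the
isometric hyperboloid→ball projection used for 2-D display.

All functions operate on the last axis and therefore accept a single
point (1-D) or a batch of points (2-D). The ``pairwise_*`` and
``*_from_tangent`` helpers additionally accept autodiff tensors so the
training loss can differentiate through them.

Numerical guards: arcosh arguments are clamped to ≥ 1 + tiny, and ball
points are clipped just inside the boundary before distance evaluation —
the hyperboloid form exists precisely because the ball distance is
division-heavy near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

ACOSH_EPS = 1e-15      # clamp for arcosh arguments (exact evaluation paths)
ACOSH_EPS_GRAD = 1e-12  # slightly wider clamp inside the training tape
BALL_EPS = 1e-5        # points clipped to radius (1 - BALL_EPS)/sqrt(K)

MANIFOLD_KINDS = ("euclidean", "poincare", "lorentz")


@dataclass
class ManifoldSpec:
    """Descriptor of the latent space.

    Parameters
    ----------
    kind:
        One of ``euclidean``, ``poincare``, ``lorentz``.
    curvature:
        Curvature magnitude K > 0; the hyperbolic spaces have curvature
        −K. Ignored for the Euclidean kind. The Lorentz closed forms
        used here are tied to the unit hyperboloid, so K must be 1 for
        that kind.
    latent_dim:
        Intrinsic dimension of the space (2 or 3 for visualization).
    """

    kind: str = "euclidean"
    curvature: float = 1.0
    latent_dim: int = 2

    def __post_init__(self):
        if self.kind not in MANIFOLD_KINDS:
            raise ValueError(f"unknown manifold kind {self.kind!r}")
        if self.curvature <= 0:
            raise ValueError("curvature magnitude K must be > 0")
        if self.kind == "lorentz" and not np.isclose(self.curvature, 1.0):
            raise ValueError(
                "the Lorentz model is implemented on the unit hyperboloid; "
                "use curvature=1")

    @property
    def ambient_dim(self) -> int:
        """Number of coordinates stored per point."""
        return self.latent_dim + 1 if self.kind == "lorentz" else self.latent_dim

    def to_dict(self) -> dict:
        return {"kind": self.kind, "curvature": self.curvature,
                "latent_dim": self.latent_dim}

    @classmethod
    def from_dict(cls, d: dict) -> "ManifoldSpec":
        return cls(kind=d["kind"], curvature=float(d["curvature"]),
                   latent_dim=int(d["latent_dim"]))


# ---------------------------------------------------------------------
# point-pair distances (numpy)
# ---------------------------------------------------------------------

def _check_same_dim(x, y):
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} vs {y.shape[-1]}")
    return x, y


def euclidean_distance(x, y):
    """Straight-line geodesic distance √((x−y)ᵀ(x−y))."""
    x, y = _check_same_dim(x, y)
    return np.sqrt(np.sum((x - y) ** 2, axis=-1))


def poincare_distance(x, y, K: float = 1.0):
    """Geodesic distance in the Poincaré ball of curvature −K.

    (1/√K)·arcosh(1 + 2K‖x−y‖² / ((1−K‖x‖²)(1−K‖y‖²)))
    """
    x, y = _check_same_dim(x, y)
    nx = np.sum(x * x, axis=-1)
    ny = np.sum(y * y, axis=-1)
    if np.any(K * nx >= 1.0) or np.any(K * ny >= 1.0):
        raise ValueError("point outside the open ball of radius 1/sqrt(K)")
    d2 = np.sum((x - y) ** 2, axis=-1)
    arg = 1.0 + 2.0 * K * d2 / ((1.0 - K * nx) * (1.0 - K * ny))
    return np.arccosh(np.maximum(arg, 1.0)) / np.sqrt(K)


def lorentz_inner(x, y):
    """Lorentzian scalar product −x₀y₀ + Σ_{i≥1} x_i y_i."""
    x, y = _check_same_dim(x, y)
    if x.shape[-1] < 2:
        raise ValueError("Lorentz ambient dimension must be >= 2")
    s = np.sum(x * y, axis=-1)
    return s - 2.0 * x[..., 0] * y[..., 0]


def on_hyperboloid(x, tol: float = 1e-6) -> bool:
    """Whether every point satisfies ⟨x,x⟩_L = −1 with x₀ > 0."""
    x = np.asarray(x, dtype=float)
    return bool(np.all(np.abs(lorentz_inner(x, x) + 1.0) <= tol)
                and np.all(x[..., 0] > 0))


def lorentz_distance(x, y, K: float = 1.0, tol: float = 1e-6):
    """Hyperboloid geodesic distance √K·arcosh(−⟨x,y⟩_L / K)."""
    x, y = _check_same_dim(x, y)
    if not (on_hyperboloid(x, tol) and on_hyperboloid(y, tol)):
        raise ValueError("input not on the hyperboloid sheet ⟨x,x⟩=-1, x0>0")
    arg = -lorentz_inner(x, y) / K
    return np.sqrt(K) * np.arccosh(np.maximum(arg, 1.0))


def manifold_distance(x, y, spec: ManifoldSpec):
    """Distance under the metric named by ``spec``."""
    if spec.kind == "euclidean":
        return euclidean_distance(x, y)
    if spec.kind == "poincare":
        return poincare_distance(x, y, spec.curvature)
    return lorentz_distance(x, y, spec.curvature)


# ---------------------------------------------------------------------
# Möbius addition and exponential maps
# ---------------------------------------------------------------------

def mobius_add(x, y, K: float = 1.0, printed_sign: bool = False):
    """Gyrogroup addition x ⊕_K y in the Poincaré ball.

    Standard form (default): numerator coefficient on x is
    1 + 2K⟨x,y⟩ + K‖y‖². With ``printed_sign=True`` the sign of the
    K‖y‖² term flips to −; that variant breaks the left-inverse identity
    (−x)⊕x = 0 and is retained only for comparison.
    """
    x, y = _check_same_dim(x, y)
    xy = np.sum(x * y, axis=-1, keepdims=True)
    nx = np.sum(x * x, axis=-1, keepdims=True)
    ny = np.sum(y * y, axis=-1, keepdims=True)
    sign = -1.0 if printed_sign else 1.0
    num = (1.0 + 2.0 * K * xy + sign * K * ny) * x + (1.0 - K * nx) * y
    den = 1.0 + 2.0 * K * xy + K ** 2 * nx * ny
    out = num / den
    # guard against rounding pushing the result onto/over the boundary
    r = np.sqrt(np.sum(out * out, axis=-1, keepdims=True))
    rmax = (1.0 - BALL_EPS) / np.sqrt(K)
    scale = np.where(r > rmax, rmax / np.maximum(r, 1e-300), 1.0)
    return out * scale


def exp_map(spec: ManifoldSpec, base, v):
    """Exponential map exp_base(v) on the manifold named by ``spec``.

    Euclidean: base + v. Poincaré: base ⊕_K tanh(√K λ‖v‖/2)·v/(√K‖v‖).
    Lorentz: cosh(‖v‖_L/√K)·base + √K sinh(‖v‖_L/√K)·v/‖v‖_L, with v a
    tangent vector at base (⟨base, v⟩_L = 0).
    """
    base, v = _check_same_dim(base, v)
    if spec.kind == "euclidean":
        return base + v
    K = spec.curvature
    if spec.kind == "poincare":
        nb2 = np.sum(base * base, axis=-1, keepdims=True)
        if np.any(K * nb2 >= 1.0):
            raise ValueError("base point outside the open ball")
        nv = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
        if np.all(nv == 0):
            return base.copy()
        lam = 2.0 / (1.0 - K * nb2)
        nv_safe = np.maximum(nv, 1e-300)
        second = np.tanh(np.sqrt(K) * lam * nv / 2.0) * v / (np.sqrt(K) * nv_safe)
        return mobius_add(base, second, K)
    # lorentz
    if not on_hyperboloid(base):
        raise ValueError("base point not on the hyperboloid")
    tangency = lorentz_inner(base, v)
    if np.any(np.abs(tangency) > 1e-8 * (1.0 + np.abs(v).max())):
        raise ValueError("v is not tangent to the hyperboloid at base")
    nv2 = lorentz_inner(v, v)  # >= 0 on the tangent space
    nv = np.sqrt(np.maximum(nv2, 0.0))[..., None]
    nv_safe = np.maximum(nv, 1e-300)
    sK = np.sqrt(K)
    out = np.cosh(nv / sK) * base + sK * np.sinh(nv / sK) * v / nv_safe
    # renormalize onto the sheet against rounding drift
    out[..., 0] = np.sqrt(1.0 + np.sum(out[..., 1:] ** 2, axis=-1))
    return out


def lorentz_to_poincare(x, K: float = 1.0):
    """Isometric projection (x₀, x₁, …) ↦ (x₁, …)/(√K·x₀ + 1)."""
    x = np.asarray(x, dtype=float)
    if not on_hyperboloid(x):
        raise ValueError("input not on the hyperboloid sheet")
    return x[..., 1:] / (np.sqrt(K) * x[..., 0:1] + 1.0)


def poincare_to_lorentz(x, K: float = 1.0):
    """Inverse of :func:`lorentz_to_poincare` (ball → hyperboloid)."""
    x = np.asarray(x, dtype=float)
    n2 = np.sum(x * x, axis=-1, keepdims=True)
    denom = 1.0 - K * n2
    x0 = (1.0 + K * n2) / (np.sqrt(K) * denom)
    rest = 2.0 * x / denom
    return np.concatenate([x0, rest], axis=-1)


def origin(spec: ManifoldSpec):
    """The origin point: 0 for Euclidean/ball, (1, 0, …, 0) for Lorentz."""
    o = np.zeros(spec.ambient_dim)
    if spec.kind == "lorentz":
        o[0] = 1.0
    return o


# ---------------------------------------------------------------------
# batched / differentiable forms used by the training loss
# ---------------------------------------------------------------------

def project_from_tangent(spec: ManifoldSpec, V):
    """Map network outputs V (rows = tangent vectors at the origin) onto
    the manifold via the exponential map at the origin.

    Accepts an ndarray or an autodiff Tensor; Euclidean rows pass
    through unchanged.
    """
    if spec.kind == "euclidean":
        return V
    K = spec.curvature
    sK = float(np.sqrt(K))
    n2 = ad.tsum(V * V, axis=1, keepdims=True)
    sq_floor = 1e-24 if ad.asarray(V).dtype == np.float64 else 1e-12
    n = ad.sqrt(ad.clip(n2, sq_floor, None))
    if spec.kind == "poincare":
        # exp_0(v) = tanh(sqrt(K)·‖v‖) · v/(sqrt(K)‖v‖)   (λ_0 = 2);
        # the tanh argument is capped so rounding cannot reach the boundary
        t = ad.clip(sK * n, 0.0, 18.0)
        return V * (ad.tanh(t) / (sK * n))
    # lorentz: tangent at (1,0,…,0) is (0, v); ‖(0,v)‖_L = ‖v‖
    x0 = ad.cosh(n / sK)
    rest = V * (sK * ad.sinh(n / sK) / n)
    return ad.concatenate([x0, rest], axis=1)


def pairwise_sq_euclidean(Z):
    n2 = ad.tsum(Z * Z, axis=1, keepdims=True)
    D2 = n2 + n2.T - 2.0 * ad.matmul(Z, Z.T)
    return ad.clip(D2, 0.0, None)


def pairwise_distance_matrix(Z, spec: ManifoldSpec):
    """All-pairs geodesic distances; differentiable when Z is a Tensor.

    The diagonal is numerically ~0 but its gradient is cut by the
    internal clamps; loss code must mask self-pairs anyway. Clamp
    widths adapt to the input precision (single precision needs a
    wider arcosh floor than double).
    """
    K = spec.curvature
    dtype = ad.asarray(Z).dtype
    acosh_floor = 1.0 + (ACOSH_EPS_GRAD if dtype == np.float64 else 1e-6)
    sq_floor = 1e-24 if dtype == np.float64 else 1e-12
    if spec.kind == "euclidean":
        return ad.sqrt(ad.clip(pairwise_sq_euclidean(Z), sq_floor, None))
    if spec.kind == "poincare":
        n2 = ad.clip(ad.tsum(Z * Z, axis=1, keepdims=True),
                     0.0, (1.0 - BALL_EPS) ** 2 / K)
        D2 = pairwise_sq_euclidean(Z)
        denom = (1.0 - K * n2) * (1.0 - K * n2.T)
        arg = ad.clip(1.0 + 2.0 * K * D2 / denom, acosh_floor, None)
        return ad.arcosh(arg) / float(np.sqrt(K))
    # lorentz
    signs = np.ones(ad.asarray(Z).shape[1], dtype=dtype)
    signs[0] = -1.0
    G = ad.matmul(Z * signs, Z.T)
    arg = ad.clip(-G / K, acosh_floor, None)
    return float(np.sqrt(K)) * ad.arcosh(arg)
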