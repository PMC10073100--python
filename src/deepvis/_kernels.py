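"""Numba-compiled elementwise kernels for the similarity graphs/loss.

Each kernel fuses a chain of elementwise operations over the n×n pair
matrices into a single memory pass. Pure-numpy fallbacks live in
:mod:`deepvis.similarity`; these are selected automatically when numba
imports. Every kernel is exercised against finite differences through
the public similarity API tests.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in normal installs
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=True, fastmath=True)
def kernel_graph_forward(D, nu, c, squared):
    """u = c·(1+arg/ν)^−(ν+1), U = 2u(1−u) with arg = D or D²."""
    n0, n1 = D.shape
    U = np.empty_like(D)
    u = np.empty_like(D)
    e = -(nu + 1.0)
    for i in range(n0):
        for j in range(n1):
            arg = D[i, j] * D[i, j] if squared else D[i, j]
            ui = c * np.exp(e * np.log1p(arg / nu))
            u[i, j] = ui
            U[i, j] = 2.0 * ui * (1.0 - ui)
    return U, u


@njit(cache=True, fastmath=True)
def kernel_graph_backward(g, u, D, nu, squared):
    """dL/dD from dL/dU, reusing u (and D for the squared variant)."""
    n0, n1 = g.shape
    out = np.empty_like(g)
    for i in range(n0):
        for j in range(n1):
            arg = D[i, j] * D[i, j] if squared else D[i, j]
            dU_darg = (2.0 - 4.0 * u[i, j]) * (
                -u[i, j] * ((nu + 1.0) / (nu + arg)))
            gd = g[i, j] * dU_darg
            if squared:
                gd *= 2.0 * D[i, j]
            out[i, j] = gd
    return out


@njit(cache=True, fastmath=True)
def gsp_terms_forward(a, b, eps, printed):
    """Masked-diagonal loss sum plus gradients in one pass."""
    n = a.shape[0]
    ga = np.empty_like(a)
    gb = np.empty_like(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                ga[i, j] = 0.0
                gb[i, j] = 0.0
                continue
            av, bv = a[i, j], b[i, j]
            ina = (av >= eps) and (av <= 1.0 - eps)
            inb = (bv >= eps) and (bv <= 1.0 - eps)
            ac = min(max(av, eps), 1.0 - eps)
            bc = min(max(bv, eps), 1.0 - eps)
            la = np.log(ac)
            lb = np.log(bc)
            l1a = np.log1p(-ac)
            l1b = np.log1p(-bc)
            if printed:
                total += ac * (la - lb) + (1.0 - bc) * (l1b - l1a)
                ga[i, j] = (la + 1.0 - lb + (1.0 - bc) / (1.0 - ac)) \
                    if ina else 0.0
                gb[i, j] = (-ac / bc - l1b - 1.0 + l1a) if inb else 0.0
            else:
                total += ac * (la - lb) + (1.0 - ac) * (l1a - l1b)
                ga[i, j] = ((la - lb) - (l1a - l1b)) if ina else 0.0
                gb[i, j] = (-ac / bc + (1.0 - ac) / (1.0 - bc)) if inb else 0.0
    return total, ga, gb


@njit(cache=True, fastmath=True)
def poincare_arg_forward(D2, den, K, floor):
    """A = max(1 + 2K·D2/(den_i·den_j), floor) and D = arcosh(A)/√K."""
    n = D2.shape[0]
    A = np.empty_like(D2)
    D = np.empty_like(D2)
    sK = np.sqrt(K)
    for i in range(n):
        for j in range(n):
            a = 1.0 + 2.0 * K * D2[i, j] / (den[i] * den[j])
            ac = a if a > floor else floor
            A[i, j] = a  # raw value kept for the clamp mask
            D[i, j] = np.arccosh(ac) / sK
    return A, D


@njit(cache=True, fastmath=True)
def poincare_arg_backward(gD, A, den, K, floor):
    """Grads wrt D2 (matrix) and n2 (vector) from dL/dD."""
    n = gD.shape[0]
    G2 = np.empty_like(gD)
    T_row = np.zeros(n)
    T_col = np.zeros(n)
    sK = np.sqrt(K)
    for i in range(n):
        for j in range(n):
            a = A[i, j]
            if a >= floor:
                ac = a if a > floor else floor
                gA = gD[i, j] / (sK * np.sqrt(ac * ac - 1.0))
            else:
                gA = 0.0
            G2[i, j] = gA * (2.0 * K) / (den[i] * den[j])
            t = gA * (a - 1.0)
            T_row[i] += t
            T_col[j] += t
    return G2, T_row, T_col
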