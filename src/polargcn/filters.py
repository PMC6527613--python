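"""Spectral graph convolutions: Chebyshev polynomial and Cayley rational filters.

Both operators realise ``y = U g(Lambda) U^T x`` for a learnable spectral
response ``g`` without ever forming the eigendecomposition: the Chebyshev
filter evaluates a degree-(K-1) polynomial of the rescaled Laplacian by the
three-term recurrence (K-hop localised, O(K|E|)); the Cayley filter
evaluates a rational function of the unscaled Laplacian through K sequential
complex linear solves with (hL + iI), where the spectral zoom h > 0 focuses
the response on low frequency bands.

These are the pure per-sample operators; the trainable layers in
:mod:`polargcn.nn` reuse the same batched kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class ChebFilterParams:
    """Chebyshev coefficients theta (K, F_in, F_out) and per-channel bias."""

    theta: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 3 or self.theta.shape[0] < 1:
            raise ValueError("theta must have shape (K>=1, F_in, F_out)")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)

    @property
    def order(self) -> int:
        return self.theta.shape[0]


@dataclass
class CayleyFilterParams:
    """Cayley coefficients: real c0, complex c_1..c_K (each F_in x F_out), zoom h."""

    c0: np.ndarray
    c: np.ndarray  # (K, F_in, F_out) complex; K may be 0
    h: float = 1.0
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c0 = np.asarray(self.c0, dtype=float)
        self.c = np.asarray(self.c, dtype=complex)
        if self.h <= 0:
            raise ValueError("spectral zoom h must be positive")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)

    @property
    def order(self) -> int:
        return self.c.shape[0]


def cheb_apply_stack(L_tilde: sp.spmatrix, x: np.ndarray, K: int) -> np.ndarray:
    """Stack [T_0(L~)x, ..., T_{K-1}(L~)x] along a new leading axis.

    ``x`` has shape (n, m); only matrix-vector products with L~ are used, so
    working storage stays O(K n m) and no polynomial of L~ is materialised.
    """
    out = np.empty((K,) + x.shape, dtype=np.result_type(L_tilde.dtype, x.dtype))
    out[0] = x
    if K > 1:
        out[1] = L_tilde @ x
    for k in range(2, K):
        out[k] = 2.0 * (L_tilde @ out[k - 1]) - out[k - 2]
    return out


def cheb_conv(x: np.ndarray, L_tilde: sp.spmatrix, params: ChebFilterParams) -> np.ndarray:
    """Chebyshev graph convolution of a signal (n, F_in) -> (n, F_out)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and L_tilde.shape[0] != 1:
        x = x.T
    K, f_in, f_out = params.theta.shape
    if x.shape != (L_tilde.shape[0], f_in):
        raise ValueError(f"signal shape {x.shape} incompatible with filter")
    stack = cheb_apply_stack(L_tilde, x, K)
    y = np.einsum("knf,kfo->no", stack, params.theta)
    if params.bias is not None:
        y = y + params.bias
    return y


def cayley_solve_factor(L: sp.spmatrix, h: float):
    """LU factorisation of (hL + iI); one solve handles both Cayley directions."""
    n = L.shape[0]
    M = (h * L + 1j * sp.identity(n)).tocsc()
    return spla.splu(M)


def cayley_conv(x: np.ndarray, L: sp.spmatrix, params: CayleyFilterParams) -> np.ndarray:
    """Cayley graph convolution of a signal (n, F_in) -> (n, F_out).

    y = x c0 + 2 Re{ sum_k (M^k x) c_k } + bias with the Cayley transform
    M = (hL - iI)(hL + iI)^{-1}, applied by sequential solves.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and L.shape[0] != 1:
        x = x.T
    f_in, f_out = params.c0.shape
    if x.shape != (L.shape[0], f_in):
        raise ValueError(f"signal shape {x.shape} incompatible with filter")
    y = x @ params.c0
    if params.order:
        lu = cayley_solve_factor(L, params.h)
        yk = x.astype(complex)
        for k in range(params.order):
            z = lu.solve(yk)
            yk = params.h * (L @ z) - 1j * z  # (hL - iI) z
            y = y + 2.0 * np.real(yk @ params.c[k])
    if params.bias is not None:
        y = y + params.bias
    return y


# ---------------------------------------------------------------------------
# Dense spectral references (test oracles, small graphs only)
# ---------------------------------------------------------------------------


def cheb_conv_dense(x: np.ndarray, L_tilde: sp.spmatrix, params: ChebFilterParams) -> np.ndarray:
    """Evaluate the Chebyshev filter through an explicit eigendecomposition."""
    lam, U = np.linalg.eigh(np.asarray(L_tilde.todense()))
    K = params.order
    T = np.empty((K, lam.size))
    T[0] = 1.0
    if K > 1:
        T[1] = lam
    for k in range(2, K):
        T[k] = 2.0 * lam * T[k - 1] - T[k - 2]
    xs = U.T @ np.atleast_2d(np.asarray(x, dtype=float))
    y = np.einsum("kn,nf,kfo->no", T, xs, params.theta)
    y = U @ y
    if params.bias is not None:
        y = y + params.bias
    return y


def cayley_conv_dense(x: np.ndarray, L: sp.spmatrix, params: CayleyFilterParams) -> np.ndarray:
    """Evaluate the Cayley filter through an explicit eigendecomposition."""
    lam, U = np.linalg.eigh(np.asarray(L.todense()))
    xs = (U.T @ np.atleast_2d(np.asarray(x, dtype=float))).astype(complex)
    mu = (params.h * lam - 1j) / (params.h * lam + 1j)
    y = (U @ xs.real) @ params.c0
    muk = np.ones_like(mu)
    for k in range(params.order):
        muk = muk * mu
        y = y + 2.0 * np.real((U @ (muk[:, None] * xs)) @ params.c[k])
    if params.bias is not None:
        y = y + params.bias
    return y


# ---------------------------------------------------------------------------
# Graph max pooling
# ---------------------------------------------------------------------------

NEG_INF = -np.inf


def graph_max_pool(x: np.ndarray, size: int) -> np.ndarray:
    """Max over contiguous sibling blocks of ``size`` nodes (axis -2).

    The signal must already be in hierarchy ``perm`` order with fake-node
    entries set to -inf so padding never wins against a real sibling.  A
    size-4 pool is two consecutive pair reductions.
    """
    if size not in (2, 4):
        raise ValueError("pooling size must be 2 or 4")
    n = x.shape[-2]
    if n % size:
        raise ValueError(f"node count {n} not divisible by pool size {size}")
    out = x
    for _ in range(size.bit_length() - 1):
        m = out.shape[-2] // 2
        out = out.reshape(out.shape[:-2] + (m, 2) + out.shape[-1:]).max(axis=-2)
    return out
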