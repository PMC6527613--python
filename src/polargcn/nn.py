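"""Minimal feed-forward neural-network engine on numpy.

The classifiers in this package are small (460-node graphs, at most ~1e6
parameters), so every layer implements an explicit forward pass and a
hand-derived backward pass; training is plain mini-batch SGD on the
categorical cross-entropy.  Everything is driven by ``numpy.random.Generator``
seeds and is bit-deterministic for a fixed seed and data order.

Layers
------
Dense, ReLU, Flatten, RasterInput, Conv2DSame, MaxPool2x2 (ceil mode) for
the grid baselines; GraphSignalInput, ChebConv, CayleyConv, GraphMaxPool
for the graph networks.  Gradient correctness is established by
finite-difference tests rather than by construction.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from . import filters
from .graph import GraphHierarchy
from .polarmap import N_RINGS, N_SECTORS

#: Compute dtype for trainable models (standard deep-learning precision).
#: The pure operators in :mod:`polargcn.filters` stay in float64; tests may
#: rebind this to float64 for high-precision finite-difference checks.
DEFAULT_DTYPE = np.float32


def _cdtype(dtype) -> type:
    return np.complex64 if np.dtype(dtype) == np.float32 else np.complex128


class Layer:
    """Base layer: named parameter and gradient arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (f_in + f_out))  # Glorot uniform
        dt = DEFAULT_DTYPE
        self.params = {
            "W": rng.uniform(-limit, limit, size=(f_in, f_out)).astype(dt),
            "b": np.zeros(f_out, dtype=dt),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ gy, "b": gy.sum(axis=0)}
        return gy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class RasterInput(Layer):
    """(B, 460) vectors -> (B, 23, 20, 1) rasters (sectors x rings)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(-1, N_RINGS, N_SECTORS).transpose(0, 2, 1)[..., None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy[..., 0].transpose(0, 2, 1).reshape(gy.shape[0], -1)


class Conv2DSame(Layer):
    """2-D convolution with odd kernel, stride 1, zero 'same' padding."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        dt = DEFAULT_DTYPE
        self.params = {
            "W": rng.uniform(-limit, limit, size=(kh * kw * c_in, c_out)).astype(dt),
            "b": np.zeros(c_out, dtype=dt),
        }

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        B = xp.shape[0]
        cols = np.empty((B, H, W, self.kh * self.kw * self.c_in), dtype=xp.dtype)
        idx = 0
        for di in range(self.kh):
            for dj in range(self.kw):
                cols[..., idx : idx + self.c_in] = xp[:, di : di + H, dj : dj + W, :]
                idx += self.c_in
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, _ = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        self._cols = self._im2col(xp, H, W)
        self._hw = (H, W)
        y = self._cols @ self.params["W"] + self.params["b"]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, H, W, _ = gy.shape
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        g2d = gy.reshape(-1, self.c_out)
        self.grads = {"W": cols2d.T @ g2d, "b": g2d.sum(axis=0)}
        gcols = (g2d @ self.params["W"].T).reshape(B, H, W, -1)
        ph, pw = self.kh // 2, self.kw // 2
        gxp = np.zeros((B, H + 2 * ph, W + 2 * pw, self.c_in), dtype=gy.dtype)
        idx = 0
        for di in range(self.kh):
            for dj in range(self.kw):
                gxp[:, di : di + H, dj : dj + W, :] += gcols[..., idx : idx + self.c_in]
                idx += self.c_in
        return gxp[:, ph : ph + H, pw : pw + W, :]


class MaxPool2x2(Layer):
    """2x2 max pooling, ceil mode (odd edges padded with -inf)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = -(-H // 2), -(-W // 2)
        xp = np.full((B, 2 * Ho, 2 * Wo, C), -np.inf, dtype=x.dtype)
        xp[:, :H, :W, :] = x
        blocks = xp.reshape(B, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(
            B, Ho, Wo, C, 4
        )
        self._arg = blocks.argmax(axis=-1)
        self._shape = (B, H, W, C)
        return blocks.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        Ho, Wo = gy.shape[1], gy.shape[2]
        gxp = np.zeros((B, 2 * Ho, 2 * Wo, C), dtype=gy.dtype)
        di, dj = self._arg // 2, self._arg % 2
        b, i, j, c = np.indices(gy.shape)
        gxp[b, 2 * i + di, 2 * j + dj, c] = gy
        return gxp[:, :H, :W, :]


class GraphSignalInput(Layer):
    """(B, 460) vectors -> (B, n0, 1) padded, permuted graph signals."""

    def __init__(self, hierarchy: GraphHierarchy) -> None:
        super().__init__()
        self.hierarchy = hierarchy
        self._real = hierarchy.perm >= 0
        self._src = hierarchy.perm[self._real]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        out = np.zeros((B, self.hierarchy.levels[0].n, 1), dtype=x.dtype)
        out[:, self._real, 0] = x[:, self._src]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros((gy.shape[0], self._src.size), dtype=gy.dtype)
        gx[:, self._src] = gy[:, self._real, 0]
        return gx


def _apply_node_op(op, x: np.ndarray) -> np.ndarray:
    """Apply an (n x n) linear operator along axis 1 of a (B, n, F) tensor."""
    B, n, F = x.shape
    flat = x.transpose(1, 0, 2).reshape(n, B * F)
    out = op(flat)
    return out.reshape(n, B, F).transpose(1, 0, 2)


class ChebConv(Layer):
    """Trainable Chebyshev graph convolution on batched signals."""

    def __init__(
        self,
        L_tilde: sp.spmatrix,
        K: int,
        f_in: int,
        f_out: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if K < 1:
            raise ValueError("Chebyshev order must be >= 1")
        dt = DEFAULT_DTYPE
        self.L = L_tilde.tocsr().astype(dt)
        # He-style uniform: the layer feeds a ReLU stack, so the
        # variance-preserving scale carries the sqrt(2) ReLU gain
        scale = np.sqrt(6.0 / (K * f_in))
        self.params = {
            "theta": rng.uniform(-scale, scale, size=(K, f_in, f_out)).astype(dt),
            "b": np.zeros(f_out, dtype=dt),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        K, f_in, f_out = self.params["theta"].shape
        B, n, F = x.shape
        flat = x.transpose(1, 0, 2).reshape(n, B * F)
        stack = filters.cheb_apply_stack(self.L, flat, K)
        # (B, n, K*F) layout turns the filter application into one GEMM
        self._stack = np.ascontiguousarray(
            stack.reshape(K, n, B, F).transpose(2, 1, 0, 3)
        ).reshape(B, n, K * F)
        W = self.params["theta"].reshape(K * f_in, f_out)
        return self._stack @ W + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        theta = self.params["theta"]
        K, f_in, f_out = theta.shape
        B, n, Fo = gy.shape
        g2d = gy.reshape(B * n, Fo)
        self.grads = {
            "theta": (self._stack.reshape(B * n, K * f_in).T @ g2d).reshape(
                K, f_in, f_out
            ),
            "b": gy.sum(axis=(0, 1)),
        }
        gflat = gy.transpose(1, 0, 2).reshape(n, B * Fo)
        gstack = filters.cheb_apply_stack(self.L, gflat, K)
        G = np.ascontiguousarray(
            gstack.reshape(K, n, B, Fo).transpose(2, 1, 0, 3)
        ).reshape(B, n, K * Fo)
        theta_t = np.ascontiguousarray(theta.transpose(0, 2, 1)).reshape(K * f_out, f_in)
        return G @ theta_t


class CayleyConv(Layer):
    """Trainable Cayley graph convolution (order K, trainable zoom h)."""

    def __init__(
        self,
        L: sp.spmatrix,
        K: int,
        f_in: int,
        f_out: int,
        rng: np.random.Generator,
        h_init: float = 1.0,
    ) -> None:
        super().__init__()
        if K < 0:
            raise ValueError("Cayley order must be >= 0")
        dt = DEFAULT_DTYPE
        self.Lmat = L.tocsr().astype(dt)
        self.K = K
        # 2K+1 effective real coefficient planes (c0 + Re/Im of c_1..c_K)
        scale = np.sqrt(6.0 / ((2 * K + 1) * f_in))
        self.params = {
            "c0": rng.uniform(-scale, scale, size=(f_in, f_out)).astype(dt),
            "c": (
                rng.uniform(-scale, scale, size=(K, f_in, f_out))
                + 1j * rng.uniform(-scale, scale, size=(K, f_in, f_out))
            ).astype(_cdtype(dt)),
            "h": np.array(float(h_init)),
            "b": np.zeros(f_out, dtype=dt),
        }

    def _factor(self):
        return filters.cayley_solve_factor(self.Lmat, float(self.params["h"]))

    def forward(self, x: np.ndarray) -> np.ndarray:
        c0, c, b = self.params["c0"], self.params["c"], self.params["b"]
        h = float(self.params["h"])
        y = x @ c0 + b
        self._x = x
        self._Y = []  # Y_k = M^k x, complex (B,n,Fin)
        self._Z = []  # z_k = (hL+iI)^{-1} Y_{k-1}
        if self.K:
            self._lu = self._factor()
            yk = x.astype(_cdtype(x.dtype))
            for k in range(self.K):
                z = _apply_node_op(self._lu.solve, yk)
                yk = h * _apply_node_op(self.Lmat.__matmul__, z) - 1j * z
                self._Z.append(z)
                self._Y.append(yk)
                y = y + 2.0 * np.real(yk @ c[k])
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c0, c = self.params["c0"], self.params["c"]
        h = float(self.params["h"])
        x = self._x
        grads = {
            "c0": np.einsum("bnf,bno->fo", x, gy),
            "b": gy.sum(axis=(0, 1)),
            "c": np.zeros_like(c),
            "h": np.zeros(()),
        }
        gx = gy @ c0.T
        if self.K:
            lu = self._lu

            def m_adjoint(v):  # M^H v = (hL + iI)(hL - iI)^{-1} v, M unitary
                z = np.conj(lu.solve(np.conj(v)))
                return h * (self.Lmat @ z) + 1j * z

            gacc = np.zeros_like(self._Y[0])
            gh = 0.0
            for k in range(self.K - 1, -1, -1):
                grads["c"][k] = 2.0 * np.einsum("bnf,bno->fo", np.conj(self._Y[k]), gy)
                gacc = gacc + 2.0 * (gy @ np.conj(c[k]).T)
                # dM/dh Y_{k-1} = 2i (hL+iI)^{-1} L z_k
                w = 2j * _apply_node_op(
                    lambda v: lu.solve(np.asarray(self.Lmat @ v)), self._Z[k]
                )
                gh += np.real(np.conj(gacc) * w).sum()
                gacc = _apply_node_op(m_adjoint, gacc)
            grads["h"] = np.array(gh)
            gx = gx + np.real(gacc)
        self.grads = grads
        return gx


class GraphMaxPool(Layer):
    """Pool contiguous sibling blocks; fake nodes never beat real siblings."""

    def __init__(self, size: int, fake_in: np.ndarray, fake_out: np.ndarray) -> None:
        super().__init__()
        if size not in (2, 4):
            raise ValueError("pooling size must be 2 or 4")
        self.size = size
        self.fake_in = np.asarray(fake_in, dtype=bool)
        self.fake_out = np.asarray(fake_out, dtype=bool)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, n, F = x.shape
        if n % self.size:
            raise ValueError(f"node count {n} not divisible by {self.size}")
        xm = x.copy()
        xm[:, self.fake_in, :] = -np.inf
        blocks = xm.reshape(B, n // self.size, self.size, F)
        self._arg = blocks.argmax(axis=2)
        out = blocks.max(axis=2)
        out[:, self.fake_out, :] = 0.0  # all-fake blocks carry no signal
        self._nshape = (B, n, F)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, n, F = self._nshape
        g = gy.copy()
        g[:, self.fake_out, :] = 0.0
        gx = np.zeros((B, n // self.size, self.size, F), dtype=gy.dtype)
        b, m, f = np.indices(gy.shape)
        gx[b, m, self._arg, f] = g
        return gx.reshape(B, n, F)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Model:
    """A plain layer stack with softmax cross-entropy head."""

    def __init__(self, layers: list[Layer], dtype=None) -> None:
        self.layers = layers
        self.dtype = dtype or DEFAULT_DTYPE

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[start : start + batch_size])))
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class decisions; an exact 0.5/0.5 tie resolves to class 0 (normal)."""
        proba = self.predict_proba(x)
        return (proba[:, 1] > 0.5).astype(int)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean categorical cross-entropy; leaves gradients in the layers."""
        logits = self.forward(x)
        p = softmax(logits)
        B = len(y)
        eps = 1e-12
        loss = -np.log(p[np.arange(B), y] + eps).mean()
        g = p.copy()
        g[np.arange(B), y] -= 1.0
        g /= B
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return float(loss)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for name, p in layer.params.items():
                p -= lr * layer.grads[name]

    # -- checkpoint support -------------------------------------------------

    def n_parameters(self) -> int:
        total = 0
        for layer in self.layers:
            for p in layer.params.values():
                n = int(np.prod(p.shape)) if p.shape else 1
                if np.iscomplexobj(p):
                    n *= 2  # real + imaginary part are separate scalars
                total += n
        return total

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"layer{i:02d}.{name}"] = p.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(state[f"layer{i:02d}.{name}"])
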