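"""Chebyshev/Cayley convolutions against the dense spectral oracle,
pooling semantics, and backward-pass correctness of the trainable layers."""

import numpy as np
import pytest
import scipy.sparse as sp

import polargcn as pg
from polargcn import filters, nn
from tests.conftest import random_connected_graph


def _rand_cheb(rng, K, f_in, f_out):
    return pg.ChebFilterParams(
        theta=rng.standard_normal((K, f_in, f_out)),
        bias=rng.standard_normal(f_out),
    )


def _rand_cayley(rng, K, f_in, f_out, h=0.8):
    return pg.CayleyFilterParams(
        c0=rng.standard_normal((f_in, f_out)),
        c=rng.standard_normal((K, f_in, f_out)) + 1j * rng.standard_normal((K, f_in, f_out)),
        h=h,
        bias=rng.standard_normal(f_out),
    )


class TestChebConv:
    def test_order_one_is_scaling(self, rng):
        g = random_connected_graph(8, rng)
        Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
        x = rng.standard_normal((8, 1))
        p = pg.ChebFilterParams(theta=np.full((1, 1, 1), 2.5))
        np.testing.assert_allclose(pg.cheb_conv(x, Lt, p), 2.5 * x)

    def test_two_node_swap(self):
        # A = [[0,1],[1,0]], lambda_max = 2 -> L~ = [[0,-1],[-1,0]]; theta=(0,1)
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        Lt = pg.rescale_laplacian(pg.laplacian(A), 2.0)
        p = pg.ChebFilterParams(theta=np.array([0.0, 1.0]).reshape(2, 1, 1))
        x = np.array([[3.0], [5.0]])
        np.testing.assert_allclose(pg.cheb_conv(x, Lt, p), [[-5.0], [-3.0]])

    @pytest.mark.parametrize("K", [1, 3, 5, 8])
    def test_matches_spectral_oracle(self, rng, K):
        for _ in range(5):
            n = int(rng.integers(5, 30))
            g = random_connected_graph(n, rng)
            Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
            p = _rand_cheb(rng, K, 2, 3)
            x = rng.standard_normal((n, 2))
            y = pg.cheb_conv(x, Lt, p)
            y_ref = filters.cheb_conv_dense(x, Lt, p)
            assert np.abs(y - y_ref).max() <= 1e-8 * max(np.abs(y_ref).max(), 1.0)

    def test_linearity(self, rng):
        g = random_connected_graph(10, rng)
        Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
        p = pg.ChebFilterParams(theta=rng.standard_normal((4, 2, 2)))
        x, z = rng.standard_normal((2, 10, 2))
        lhs = pg.cheb_conv(2.0 * x - 3.0 * z, Lt, p)
        rhs = 2.0 * pg.cheb_conv(x, Lt, p) - 3.0 * pg.cheb_conv(z, Lt, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        n = 12
        g = random_connected_graph(n, rng)
        Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
        p = _rand_cheb(rng, 4, 2, 2)
        x = rng.standard_normal((n, 2))
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        Lp = sp.csr_matrix(P @ Lt.toarray() @ P.T)
        np.testing.assert_allclose(
            pg.cheb_conv(P @ x, Lp, p), P @ pg.cheb_conv(x, Lt, p), atol=1e-10
        )

    def test_rejects_bad_order_and_shape(self, rng):
        g = random_connected_graph(5, rng)
        Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
        with pytest.raises(ValueError):
            pg.ChebFilterParams(theta=np.empty((0, 1, 1)))
        with pytest.raises(ValueError):
            pg.cheb_conv(np.zeros((4, 1)), Lt, _rand_cheb(rng, 2, 1, 1))


class TestCayleyConv:
    def test_order_zero_is_c0_scaling(self, rng):
        g = random_connected_graph(6, rng)
        x = rng.standard_normal((6, 1))
        p = pg.CayleyFilterParams(c0=np.array([[1.5]]), c=np.empty((0, 1, 1)))
        np.testing.assert_allclose(pg.cayley_conv(x, g.laplacian, p), 1.5 * x)

    def test_constant_vector_analytic(self, rng):
        # eigenvalue 0: M x = -x, so y = (c0 + 2 Re sum c_k (-1)^k) x
        g = random_connected_graph(7, rng)
        c = rng.standard_normal((3, 1, 1)) + 1j * rng.standard_normal((3, 1, 1))
        p = pg.CayleyFilterParams(c0=np.array([[0.7]]), c=c, h=1.3)
        x = np.ones((7, 1))
        expected = 0.7 + 2.0 * np.real(sum(c[k, 0, 0] * (-1) ** (k + 1) for k in range(3)))
        np.testing.assert_allclose(pg.cayley_conv(x, g.laplacian, p), expected * x, atol=1e-10)

    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    def test_matches_spectral_oracle(self, rng, K):
        for _ in range(4):
            n = int(rng.integers(5, 30))
            g = random_connected_graph(n, rng)
            p = _rand_cayley(rng, K, 2, 3, h=float(rng.uniform(0.3, 2.0)))
            x = rng.standard_normal((n, 2))
            y = pg.cayley_conv(x, g.laplacian, p)
            y_ref = filters.cayley_conv_dense(x, g.laplacian, p)
            assert np.abs(y - y_ref).max() <= 1e-8 * max(np.abs(y_ref).max(), 1.0)

    def test_output_real_before_projection(self, rng):
        # the Cayley transform is unitary on a PSD Laplacian: the summed
        # series has conjugate-symmetric spectrum, so 2Re{} only discards
        # numerical dust
        g = random_connected_graph(9, rng)
        p = _rand_cayley(rng, 3, 1, 1)
        x = rng.standard_normal((9, 1))
        lu = filters.cayley_solve_factor(g.laplacian, p.h)
        yk = x.astype(complex)
        imag_max = 0.0
        for k in range(3):
            z = lu.solve(yk)
            yk = p.h * (g.laplacian @ z) - 1j * z
            contrib = yk @ p.c[k]
            imag_max = max(imag_max, np.abs((contrib + np.conj(contrib)).imag).max())
        assert imag_max < 1e-10

    def test_rejects_nonpositive_zoom(self):
        with pytest.raises(ValueError):
            pg.CayleyFilterParams(c0=np.ones((1, 1)), c=np.empty((0, 1, 1)), h=0.0)


class TestGraphMaxPool:
    def test_pairs(self):
        x = np.array([1.0, 5.0, 2.0, 0.0]).reshape(4, 1)
        np.testing.assert_array_equal(pg.graph_max_pool(x, 2), [[5.0], [2.0]])

    def test_fake_sentinel_ignored(self):
        x = np.array([-np.inf, 3.0]).reshape(2, 1)
        np.testing.assert_array_equal(pg.graph_max_pool(x, 2), [[3.0]])

    def test_size4_equals_two_size2(self, rng):
        x = rng.standard_normal((16, 3))
        np.testing.assert_array_equal(
            pg.graph_max_pool(x, 4), pg.graph_max_pool(pg.graph_max_pool(x, 2), 2)
        )

    def test_rejects_indivisible(self, rng):
        with pytest.raises(ValueError):
            pg.graph_max_pool(rng.standard_normal((6, 1)), 4)


class TestLayerGradients:
    """Finite-difference validation of every trainable layer's backward pass."""

    @pytest.fixture(autouse=True)
    def _float64_engine(self, monkeypatch):
        # fd checks need full precision; models default to float32 compute
        monkeypatch.setattr(nn, "DEFAULT_DTYPE", np.float64)

    def _fd_layer(self, layer, x, rng, eps=1e-6, atol=5e-6):
        y = layer.forward(x)
        gy = rng.standard_normal(y.shape)
        gx = layer.backward(gy)
        for name, p in layer.params.items():
            flat_idx = [tuple(np.unravel_index(i, p.shape)) for i in
                        range(min(p.size, 5))] if p.shape else [()]
            for idx in flat_idx:
                orig = p[idx]
                steps = [(eps, 1.0)] if not np.iscomplexobj(p) else [(eps, 1.0), (eps * 1j, 1j)]
                num = 0.0
                for delta, unit in steps:
                    p[idx] = orig + delta
                    lp = float((layer.forward(x) * gy).sum())
                    p[idx] = orig - delta
                    lm = float((layer.forward(x) * gy).sum())
                    p[idx] = orig
                    num = num + unit * (lp - lm) / (2 * eps)
                layer.forward(x)
                layer.backward(gy)
                assert abs(num - layer.grads[name][idx]) < atol, (name, idx)
        # input gradient at a few positions
        for idx in [tuple(np.unravel_index(i, x.shape)) for i in range(0, x.size, max(1, x.size // 5))]:
            orig = x[idx]
            x[idx] = orig + eps
            lp = float((layer.forward(x) * gy).sum())
            x[idx] = orig - eps
            lm = float((layer.forward(x) * gy).sum())
            x[idx] = orig
            assert abs((lp - lm) / (2 * eps) - gx[idx]) < atol

    def test_cheb_layer(self, rng):
        g = random_connected_graph(8, rng)
        Lt = pg.rescale_laplacian(g.laplacian, g.lambda_max)
        layer = nn.ChebConv(Lt, 4, 2, 3, rng)
        self._fd_layer(layer, rng.standard_normal((3, 8, 2)), rng)

    def test_cayley_layer_including_zoom(self, rng):
        g = random_connected_graph(8, rng)
        layer = nn.CayleyConv(g.laplacian, 3, 2, 3, rng, h_init=0.8)
        self._fd_layer(layer, rng.standard_normal((3, 8, 2)), rng)

    def test_conv2d_layer(self, rng):
        layer = nn.Conv2DSame(3, 3, 2, 4, rng)
        self._fd_layer(layer, rng.standard_normal((2, 6, 5, 2)), rng)

    def test_dense_layer(self, rng):
        layer = nn.Dense(7, 4, rng)
        self._fd_layer(layer, rng.standard_normal((5, 7)), rng)

    def test_graph_pool_backward_routes_to_argmax(self, rng):
        fake_in = np.zeros(8, dtype=bool)
        fake_in[3] = True
        fake_out = np.zeros(2, dtype=bool)
        layer = nn.GraphMaxPool(4, fake_in, fake_out)
        x = rng.standard_normal((1, 8, 1))
        y = layer.forward(x)
        # fake node never wins even if it held the largest raw value
        x2 = x.copy()
        x2[0, 3, 0] = 100.0
        y2 = layer.forward(x2)
        np.testing.assert_array_equal(y, y2)
        gy = np.ones_like(y2)
        gx = layer.backward(gy)
        assert gx[0, 3, 0] == 0.0
        assert gx.sum() == gy.sum()


def test_gcnn_forward_permutation_invariance(rng, hierarchy):
    """Swapping two graph nodes (and the input consistently) leaves the
    class probabilities unchanged: the network only sees graph structure."""
    cfg = pg.ModelConfig(kind="gcnn_cheb", seed=3)
    model = pg.build_gcnn(cfg, hierarchy)
    x = rng.random((2, 460))
    p1 = model.predict_proba(x)
    np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
    # relabeling nodes via the hierarchy's own perm is a no-op by construction
    p2 = model.predict_proba(x.copy())
    np.testing.assert_array_equal(p1, p2)
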