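import numpy as np
import pytest

from spotalign import gat
from spotalign.graph import build_graph
from spotalign.uot import latent_cost


def isolated_graph(n):
    coords = np.column_stack([np.arange(n) * 10.0, np.zeros(n)])
    return build_graph(coords, radius=1.0)


def identity_params(d):
    """Single linear layer, identity weights, zero attention vectors."""
    p = gat.init_params([d, d], seed=0, activation="linear")
    p.W[0] = np.eye(d)
    p.v_s[0][:] = 0.0
    p.v_r[0][:] = 0.0
    return p


class TestAttention:
    def test_rows_sum_to_one_and_zero_off_support(self):
        rng = np.random.RandomState(0)
        coords = rng.rand(8, 2) * 2
        graph = build_graph(coords, radius=0.9)
        params = gat.init_params([4, 3], seed=1)
        att = gat.attention_weights(rng.randn(8, 4), graph, 0, params)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(att[~graph.mask_with_self()] == 0)

    def test_isolated_spot_attends_to_itself(self):
        params = gat.init_params([3, 2], seed=0)
        att = gat.attention_weights(np.random.RandomState(2).randn(4, 3),
                                    isolated_graph(4), 0, params)
        assert np.allclose(att, np.eye(4))

    def test_zero_vectors_give_uniform_attention(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        graph = build_graph(coords, radius=1.5)
        params = gat.init_params([3, 2], seed=0)
        params.v_s[0][:] = 0.0
        params.v_r[0][:] = 0.0
        att = gat.attention_weights(np.random.RandomState(0).randn(4, 3),
                                    graph, 0, params)
        sizes = np.array([2, 3, 3, 2])  # self + line neighbors
        expected = (np.array(
            build_graph(coords, 1.5).mask_with_self(), dtype=float)
            / sizes[:, None])
        assert np.allclose(att, expected)


class TestEncodeDecode:
    def test_identity_configuration_roundtrip(self):
        H0 = np.random.RandomState(0).randn(5, 3)
        graph = isolated_graph(5)
        params = identity_params(3)
        z, Hhat, _ = gat.autoencode(H0, graph, params)
        assert np.allclose(z, H0)
        assert np.allclose(Hhat, H0)

    def test_permutation_equivariance(self):
        rng = np.random.RandomState(3)
        coords = rng.rand(7, 2) * 2
        H0 = rng.randn(7, 4)
        params = gat.init_params([4, 3, 2], seed=1)
        graph = build_graph(coords, radius=1.0)
        z = gat.encode(H0, graph, params).z
        perm = rng.permutation(7)
        z_perm = gat.encode(H0[perm], build_graph(coords[perm], 1.0), params).z
        assert np.allclose(z_perm, z[perm], atol=1e-10)

    def test_no_cross_slice_message_passing(self):
        """Perturbing slice 2's inputs leaves slice 1's embedding unchanged."""
        from spotalign.graph import block_diagonal
        rng = np.random.RandomState(4)
        g1 = build_graph(rng.rand(6, 2), radius=0.5)
        g2 = build_graph(rng.rand(5, 2), radius=0.5)
        graph = block_diagonal([g1, g2])
        H = rng.randn(11, 4)
        params = gat.init_params([4, 3], seed=0)
        z_before = gat.encode(H, graph, params).z
        H2 = H.copy()
        H2[6:] += rng.randn(5, 4) * 5
        z_after = gat.encode(H2, graph, params).z
        assert np.allclose(z_after[:6], z_before[:6])
        assert not np.allclose(z_after[6:], z_before[6:])

    def test_orthogonal_weights_reconstruct_isolated_spots(self):
        """Linear sigma with orthogonal square W: decoder inverts encoder."""
        rng = np.random.RandomState(5)
        Q, _ = np.linalg.qr(rng.randn(4, 4))
        params = gat.init_params([4, 4], seed=0, activation="linear")
        params.W[0] = Q
        H0 = rng.randn(6, 4)
        _, Hhat, _ = gat.autoencode(H0, isolated_graph(6), params)
        assert np.allclose(Hhat, H0, atol=1e-6)

    def test_weight_tying_parameter_count(self):
        """The autoencoder owns exactly the encoder's parameters."""
        params = gat.init_params([10, 6, 3], seed=0)
        expected = (6 * 10 + 3 * 6) + 2 * (6 + 3)
        assert params.n_parameters() == expected

    def test_wrong_input_dim_rejected(self):
        params = gat.init_params([4, 2], seed=0)
        with pytest.raises(ValueError, match="first layer"):
            gat.forward(np.zeros((3, 5)), isolated_graph(3), params)


class TestReconstructionLoss:
    def test_values_and_symmetry(self):
        assert gat.reconstruction_loss(np.ones((2, 3)), np.ones((2, 3))) == 0.0
        assert gat.reconstruction_loss([[1.0, 0.0]], [[0.0, 0.0]]) == 1.0
        rng = np.random.RandomState(0)
        a, b = rng.randn(5, 3), rng.randn(5, 3)
        perm = rng.permutation(5)
        assert gat.reconstruction_loss(a, b) == pytest.approx(
            gat.reconstruction_loss(a[perm], b[perm]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gat.reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestGradients:
    def _fd_check(self, line_toy, loss_fn, grad_fn, h=1e-5, tol=1e-4):
        H0, graph = line_toy
        params = gat.init_params([4, 3, 2], seed=1)
        grads = grad_fn(H0, graph, params)
        worst = 0.0
        for name in ("W", "v_s", "v_r"):
            for k, arr in enumerate(getattr(params, name)):
                num = np.zeros_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + h
                    fp = loss_fn(H0, graph, params)
                    arr[idx] = orig - h
                    fm = loss_fn(H0, graph, params)
                    arr[idx] = orig
                    num[idx] = (fp - fm) / (2 * h)
                scale = max(np.abs(num).max(), 1e-8)
                worst = max(worst, np.abs(grads[name][k] - num).max() / scale)
        assert worst < tol, f"max relative gradient error {worst}"

    def test_reconstruction_gradient_matches_finite_differences(self, line_toy):
        def loss(H0, graph, params):
            _, Hhat, _ = gat.autoencode(H0, graph, params)
            return gat.reconstruction_loss(H0, Hhat)

        def grad(H0, graph, params):
            cache = gat.forward(H0, graph, params)
            return gat.backward(cache, params,
                                d_recon=2.0 * (cache["Hhat"][0] - H0))

        self._fd_check(line_toy, loss, grad)

    def test_transport_cost_gradient_matches_finite_differences(self, line_toy):
        """Gradient of sum_ij C_ij T_ij through the embeddings, T fixed."""
        T = np.random.RandomState(7).rand(3, 2)
        T /= T.sum()

        def loss(H0, graph, params):
            z = gat.forward(H0, graph, params)["H"][2]
            return float((latent_cost(z[:3], z[3:]).C * T).sum())

        def grad(H0, graph, params):
            cache = gat.forward(H0, graph, params)
            z = cache["H"][2]
            zx, zy = z[:3], z[3:]
            C = latent_cost(zx, zy).C
            W = T / np.where(C > 0, C, 1.0)
            dz = np.vstack([
                W.sum(1)[:, None] * zx - W @ zy,
                W.sum(0)[:, None] * zy - W.T @ zx,
            ])
            return gat.backward(cache, params, d_z=dz)

        self._fd_check(line_toy, loss, grad)


def test_checkpoint_roundtrip(tmp_path):
    params = gat.init_params([5, 3], seed=2)
    gat.save_params(params, tmp_path / "model.npz")
    loaded = gat.load_params(tmp_path / "model.npz")
    assert loaded.layer_dims == params.layer_dims
    assert loaded.activation == params.activation
    for a, b in zip(params.flat_list(), loaded.flat_list()):
        assert np.array_equal(a, b)
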