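import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trend.encoder import (
    EncoderConfig,
    TransformerEncoder,
    positional_encoding,
    sdpa,
    window_series,
)
from trend.graph import NetworkGraph
from trend.params import ParamBounds


@pytest.fixture()
def masked_graph():
    a_mask = np.array([[0, 0, 1], [0, 0, 0], [1, 1, 0]], dtype=np.int8)
    return NetworkGraph(3, a_mask, c_mask=np.array([[1, 0], [0, 1], [0, 0]], dtype=np.int8))


class TestWindowing:
    def test_single_window_when_T_equals_N(self):
        b = window_series(np.zeros((30, 2)), 30)
        assert b.n_windows == 1 and b.pad_len == 0

    def test_enumerated_stride_one_cover(self):
        # T=100, N=20, 95% overlap -> stride 1, starts 0..80, none padded
        b = window_series(np.arange(200).reshape(100, 2), 20, 0.95)
        assert b.stride == 1
        assert b.n_windows == 81
        assert b.pad_len == 0
        # each window is the contiguous chunk starting at its index
        for w in (0, 37, 80):
            np.testing.assert_array_equal(
                b.windows[w], np.arange(200).reshape(100, 2)[w : w + 20]
            )

    def test_final_window_zero_padded(self):
        b = window_series(np.ones((19, 1)), 20)
        assert b.n_windows == 1
        assert b.pad_len == 1
        assert b.windows[0, -1, 0] == 0.0

    def test_degenerate_window_length_rejected(self):
        with pytest.raises(ValueError):
            window_series(np.ones((5, 1)), 21)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(10, 200), st.integers(2, 40))
    def test_windows_tile_the_series(self, T, N):
        if N > 4 * T:
            return
        Y = np.arange(T, dtype=float).reshape(T, 1)
        b = window_series(Y, N)
        # every sample index appears in at least one window
        covered = np.zeros(T, dtype=bool)
        starts = [k * b.stride for k in range(b.n_windows)]
        for s in starts:
            covered[s : s + N] = True
        assert covered.all()
        # only the last window may be padded
        assert b.windows.shape == (b.n_windows, N, 1)


class TestPositionalEncoding:
    def test_position_zero_pattern(self):
        pe = positional_encoding(4, 6)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)  # sin 0
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)  # cos 0

    def test_known_value_and_range(self):
        pe = positional_encoding(8, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert np.all((pe >= -1) & (pe <= 1))

    def test_odd_dimension_supported(self):
        assert positional_encoding(5, 3).shape == (5, 3)


class TestSDPA:
    def test_uniform_attention_for_identical_keys(self):
        Q = np.random.default_rng(0).standard_normal((4, 2))
        K = np.ones((3, 2))
        V = np.arange(6, dtype=float).reshape(3, 2)
        A, out = sdpa(Q, K, V)
        np.testing.assert_allclose(A, 1 / 3)
        np.testing.assert_allclose(out, np.tile(V.mean(0), (4, 1)))

    def test_mask_selects_single_key(self):
        mask = np.array([-np.inf, 0.0, -np.inf])
        Q = np.zeros((2, 2))
        K = np.random.default_rng(1).standard_normal((3, 2))
        V = np.random.default_rng(2).standard_normal((3, 2))
        A, out = sdpa(Q, K, V, mask=mask)
        np.testing.assert_allclose(A[:, 1], 1.0)
        np.testing.assert_allclose(out, np.tile(V[1], (2, 1)))

    def test_two_by_two_hand_computed(self):
        # d_k = 1: A = softmax([[q1 k1, q1 k2], [q2 k1, q2 k2]])
        Q = np.array([[1.0], [2.0]])
        K = np.array([[0.5], [-1.0]])
        V = np.array([[1.0], [10.0]])
        A, out = sdpa(Q, K, V)
        z = np.array([[0.5, -1.0], [1.0, -2.0]])
        expected = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(A, expected, atol=1e-12)
        np.testing.assert_allclose(out, expected @ V, atol=1e-12)

    def test_inconsistent_dims_rejected(self):
        with pytest.raises(ValueError):
            sdpa(np.zeros((2, 3)), np.zeros((4, 2)), np.zeros((4, 2)))


class TestEncoderBlocks:
    def test_shapes_preserved_and_maps_stochastic(self, masked_graph):
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=3))
        batch = window_series(np.random.default_rng(0).standard_normal((40, 3)), 16)
        H_asa, H_ana, maps = enc.forward(batch)
        assert H_asa.data.shape == batch.windows.shape
        assert H_ana.data.shape == batch.windows.shape
        np.testing.assert_allclose(maps.asa.sum(-1), 1.0, atol=1e-10)
        np.testing.assert_allclose(maps.ana.sum(-1), 1.0, atol=1e-10)

    def test_ana_mask_soundness(self, masked_graph):
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=3))
        batch = window_series(np.random.default_rng(0).standard_normal((40, 3)), 16)
        _, _, maps = enc.forward(batch)
        permitted = masked_graph.a_mask.astype(bool) | np.eye(3, dtype=bool)
        assert np.all(maps.ana[:, ~permitted] == 0.0)

    def test_self_only_mask_forces_identity(self):
        graph = NetworkGraph(2, np.zeros((2, 2), dtype=np.int8))
        enc = TransformerEncoder(graph, N=8, cfg=EncoderConfig(seed=0))
        batch = window_series(np.random.default_rng(1).standard_normal((8, 2)), 8)
        _, _, maps = enc.forward(batch)
        np.testing.assert_allclose(maps.ana, np.eye(2)[None], atol=1e-12)

    def test_embedding_scales_single_column(self, masked_graph):
        cfg = EncoderConfig(seed=0, use_positional=False)
        enc = TransformerEncoder(masked_graph, N=8, cfg=cfg)
        batch = window_series(np.random.default_rng(2).standard_normal((8, 3)), 8)
        out_identity = enc.embed(batch.windows).data
        np.testing.assert_array_equal(out_identity, batch.windows)
        enc.weights["embed"].data = np.array([1.0, 2.0, 1.0])
        doubled = enc.embed(batch.windows).data
        np.testing.assert_array_equal(doubled[:, :, 1], 2 * batch.windows[:, :, 1])
        np.testing.assert_array_equal(doubled[:, :, 0], batch.windows[:, :, 0])

    def test_layer_norm_contract(self, masked_graph):
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=5))
        batch = window_series(np.random.default_rng(3).standard_normal((40, 3)), 16)
        H_asa, _, _ = enc.forward(batch)
        # post-LN features have per-position mean ~0 and sd ~1
        np.testing.assert_allclose(H_asa.data.mean(-1), 0.0, atol=1e-7)
        np.testing.assert_allclose(H_asa.data.std(-1), 1.0, atol=1e-2)


class TestDecode:
    def test_neutral_raw_decodes_to_midpoints_and_zero_edges(self, masked_graph):
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=0))
        batch = window_series(np.zeros((40, 3)), 16)
        # zero-initialized heads: raw is exactly 0
        theta, _ = enc.encode(batch)
        b = ParamBounds()
        np.testing.assert_allclose(theta.neuronal.sigma, np.mean(b.sigma))
        np.testing.assert_allclose(theta.neuronal.lambda_, np.mean(b.lambda_))
        np.testing.assert_allclose(theta.neuronal.mu, np.mean(b.mu))
        np.testing.assert_array_equal(
            theta.conn.A[masked_graph.a_mask.astype(bool)], 0.0
        )

    def test_decoded_values_respect_bounds_and_mask(self, masked_graph):
        rng = np.random.default_rng(7)
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=7))
        # randomize the heads so raw values are arbitrary
        for name in ("summ_asa_W", "summ_asa_b", "summ_ana_W", "summ_ana_b"):
            enc.weights[name].data = 10 * rng.standard_normal(
                enc.weights[name].data.shape
            )
        batch = window_series(rng.standard_normal((40, 3)), 16)
        theta, _ = enc.encode(batch)
        b = ParamBounds()
        assert np.all((theta.neuronal.sigma > b.sigma[0]) & (theta.neuronal.sigma < b.sigma[1]))
        assert np.all((theta.neuronal.lambda_ > b.lambda_[0]) & (theta.neuronal.lambda_ < b.lambda_[1]))
        assert np.all((theta.neuronal.mu > b.mu[0]) & (theta.neuronal.mu < b.mu[1]))
        assert np.all(np.abs(theta.conn.A) <= b.a_max)
        assert np.all(theta.conn.A[~masked_graph.a_mask.astype(bool)] == 0.0)

    def test_theta_dimension(self, masked_graph):
        enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=0))
        batch = window_series(np.random.default_rng(0).standard_normal((40, 3)), 16)
        theta, _ = enc.encode(batch)
        assert theta.vector.size == 3 * 3 + masked_graph.n_a_edges

    def test_seed_determinism(self, masked_graph):
        batch = window_series(np.random.default_rng(0).standard_normal((40, 3)), 16)
        outs = []
        for _ in range(2):
            enc = TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(seed=11))
            theta, _ = enc.encode(batch)
            outs.append(theta.vector)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_heads_must_divide_regions(self, masked_graph):
        with pytest.raises(ValueError):
            TransformerEncoder(masked_graph, N=16, cfg=EncoderConfig(n_heads=2))

    def test_full_embedding_ablation_runs(self, masked_graph):
        cfg = EncoderConfig(seed=0, diagonal_embedding=False)
        enc = TransformerEncoder(masked_graph, N=16, cfg=cfg)
        assert enc.weights["embed"].data.shape == (3, 3)
        batch = window_series(np.random.default_rng(0).standard_normal((40, 3)), 16)
        theta, _ = enc.encode(batch)
        assert np.all(np.isfinite(theta.vector))
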