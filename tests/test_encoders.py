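"""Attention mechanics, SEM cell encoding, and the variational plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypergrn import autodiff as ad
from hypergrn.autodiff import Tensor
from hypergrn.data import CausalMatrix, ExpressionMatrix, GaussianLatent
from hypergrn.encoders import (
    AttentionParams,
    CellEncoder,
    SemEncoderParams,
    attention_coefficients,
    attention_score,
    cell_encode_sem,
    gene_variational_head,
    propagate,
    reparameterize,
    smoothing_operator,
)
from hypergrn.io_preprocess import build_hypergraph, normalize
from hypergrn.training import TrainConfig, init_network_params


def make_attention(in_w=4, out_w=3, heads=2, rng=None):
    rng = rng or np.random.default_rng(0)
    W = Tensor(rng.normal(size=(heads, in_w, out_w)))
    a = Tensor(rng.normal(size=(heads, 2 * out_w)))
    return AttentionParams([W], [a], leak=0.2)


class TestAttentionScore:
    def test_zero_score_vector_gives_zero(self):
        params = make_attention()
        params.a[0].data[:] = 0.0
        h = np.ones(4)
        assert attention_score(h, h, params, 0, 0) == 0.0

    def test_identity_projection_selects_first_entry(self):
        W = Tensor(np.eye(3)[None])
        a = Tensor(np.concatenate([[1.0], np.zeros(5)])[None])
        params = AttentionParams([W], [a], leak=0.2)
        h_i = np.array([2.5, -1.0, 3.0])
        assert attention_score(h_i, np.zeros(3), params, 0, 0) == pytest.approx(2.5)

    def test_negative_preactivation_leaks(self):
        W = Tensor(np.eye(2)[None])
        a = Tensor(np.array([[1.0, 0.0, 0.0, 0.0]]))
        params = AttentionParams([W], [a], leak=0.2)
        out = attention_score(np.array([-5.0, 0.0]), np.zeros(2), params, 0, 0)
        assert out == pytest.approx(0.2 * -5.0)

    def test_width_mismatch_rejected(self):
        params = make_attention(in_w=4)
        with pytest.raises(ValueError):
            attention_score(np.ones(5), np.ones(5), params, 0, 0)


class TestAttentionCoefficients:
    def test_singleton_hyperedge(self):
        np.testing.assert_allclose(attention_coefficients(np.array([3.7])), [1.0])

    def test_equal_scores_split_evenly(self):
        np.testing.assert_allclose(attention_coefficients(np.zeros(2)), [0.5, 0.5])

    def test_log3_example(self):
        out = attention_coefficients(np.array([0.0, np.log(3.0)]))
        np.testing.assert_allclose(out, [0.25, 0.75])

    def test_empty_hyperedge_rejected(self):
        with pytest.raises(ValueError):
            attention_coefficients(np.array([]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance_and_normalization(self, scores, shift):
        s = np.array(scores)
        base = attention_coefficients(s)
        shifted = attention_coefficients(s + shift)
        np.testing.assert_allclose(base, shifted, atol=1e-12)
        assert np.isclose(base.sum(), 1.0)


class TestPropagate:
    def test_singleton_reduction(self):
        """One gene, one cell: output = (M Omega M^T H) W with alpha = 1."""
        raw = ExpressionMatrix(np.array([[2.0]]), ["c0"], ["g0"])
        hg = build_hypergraph(raw, normalize(raw))
        params = make_attention(in_w=1, out_w=2, heads=1)
        coeffs = np.ones((1, 1, 1))
        feats = np.array([[1.5]])
        out = propagate(feats, hg, coeffs, params, 0, activation="identity")
        S = smoothing_operator(hg.incidence)
        np.testing.assert_allclose(out, (S @ feats) @ params.W[0].data[0])

    def test_zero_features_give_zero(self, random_hypergraph):
        hg = random_hypergraph
        params = make_attention(in_w=hg.n_cells, out_w=3, heads=1,
                                rng=np.random.default_rng(1))
        co = np.einsum("ci,cj->cij", hg.incidence, hg.incidence)
        coeffs = co / np.maximum(co.sum(-1, keepdims=True), 1)
        out = propagate(np.zeros((hg.n_genes, hg.n_cells)), hg, coeffs, params, 0)
        np.testing.assert_array_equal(out, 0.0)

    def test_doubling_weights_doubles_preactivation(self, random_hypergraph):
        hg = random_hypergraph
        params = make_attention(in_w=hg.n_cells, out_w=3, heads=1,
                                rng=np.random.default_rng(2))
        co = np.einsum("ci,cj->cij", hg.incidence, hg.incidence)
        coeffs = co / np.maximum(co.sum(-1, keepdims=True), 1)
        feats = np.random.default_rng(3).normal(size=(hg.n_genes, hg.n_cells))
        base = propagate(feats, hg, coeffs, params, 0, activation="identity")
        hg.hyperedge_weights = 2.0 * np.eye(hg.n_cells)
        doubled = propagate(feats, hg, coeffs, params, 0, activation="identity")
        np.testing.assert_allclose(doubled, 2.0 * base)

    def test_coefficients_outside_incidence_rejected(self, small_hypergraph):
        hg = small_hypergraph
        bad = np.ones((hg.n_cells, hg.n_genes, hg.n_genes))
        params = make_attention(in_w=hg.n_cells, out_w=2, heads=1)
        with pytest.raises(ValueError, match="sharing no hyperedge"):
            propagate(hg.node_features, hg, bad, params, 0)


class TestEncoderCoefficientContract:
    """The factorized training path must honour the per-hyperedge softmax."""

    def _encoder(self, hg, seed=0):
        cfg = TrainConfig(seed=seed, layers=1, heads=2, attn_hidden=4,
                          latent_dim_gene=4)
        gene_enc, _, _ = init_network_params(cfg, hg.n_genes, hg.n_cells,
                                             np.random.default_rng(seed))
        return gene_enc

    def test_rows_sum_to_one_and_structural_zeros(self, random_hypergraph):
        hg = random_hypergraph
        alpha = self._encoder(hg).attention_coefficients_dense(hg)
        inc = hg.incidence
        for c in range(hg.n_cells):
            members = inc[c] > 0
            sums = alpha[:, c, members, :].sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert np.all(alpha[:, c, ~members, :] == 0.0)
            assert np.all(alpha[:, c, :, ~members] == 0.0)

    def test_factorized_layer_matches_dense_construction(self, random_hypergraph):
        """The efficient sum_c alpha factorization equals the explicit
        per-hyperedge aggregation."""
        hg = random_hypergraph
        enc = self._encoder(hg)
        enc.degree_normalize = False
        X = Tensor(hg.node_features)
        S = smoothing_operator(hg.incidence, normalized=enc.normalized_smoothing)
        got = enc._layer(X, hg.incidence, S, 0, final=True).data

        alpha = enc.attention_coefficients_dense(hg)  # (heads, cells, n, n)
        W = enc.params.W[0].data
        T = np.einsum("ij,jm,hmw->hiw", S, hg.node_features, W)
        msg = np.einsum("hcij,hjw->hciw", alpha, T)
        agg = np.einsum("hciw,ci->hiw", msg, hg.incidence)
        expected = np.where(agg > 0, agg, np.expm1(agg)).mean(axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-8)


class TestSemEncoding:
    def _params(self, n_genes, hidden=None):
        if hidden is None:
            mlp = [(Tensor(np.ones((1, 1))), Tensor(np.zeros(1)))]
        else:
            rng = np.random.default_rng(5)
            mlp = [(Tensor(rng.normal(size=(1, hidden))), Tensor(np.zeros(hidden))),
                   (Tensor(rng.normal(size=(hidden, 1))), Tensor(np.zeros(1)))]
        return SemEncoderParams(
            mlp=mlp,
            head_mu=(Tensor(np.ones(n_genes)), Tensor(np.zeros(n_genes))),
            head_sigma=(Tensor(np.zeros(n_genes)), Tensor(np.zeros(n_genes))),
        )

    def test_zero_A_is_identity_on_mlp_output(self, rng):
        n = 4
        params = self._params(n, hidden=8)
        F = rng.normal(size=(6, n))
        A = CausalMatrix(np.zeros((n, n)), [f"g{i}" for i in range(n)])
        out = cell_encode_sem(F, A, params)
        from hypergrn.encoders import _genewise_mlp_forward
        np.testing.assert_allclose(out, _genewise_mlp_forward(Tensor(F),
                                                              params.mlp).data)

    def test_upper_triangular_2x2_by_hand(self):
        """With f_E = identity and A = [[0, a], [0, 0]], the second feature
        is reduced by a times the first: z = h (I - A)."""
        a = 0.7
        params = self._params(2)
        A = CausalMatrix(np.array([[0.0, a], [0.0, 0.0]]), ["g0", "g1"])
        F = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = cell_encode_sem(F, A, params)
        expected = np.column_stack([F[:, 0], F[:, 1] - a * F[:, 0]])
        np.testing.assert_allclose(out, expected)

    def test_dimension_mismatch_rejected(self):
        params = self._params(3)
        A = CausalMatrix(np.zeros((4, 4)), [f"g{i}" for i in range(4)])
        with pytest.raises(ValueError):
            cell_encode_sem(np.ones((2, 3)), A, params)

    def test_cell_encoder_heads_positive_std(self, rng):
        n = 5
        enc = CellEncoder(self._params(n))
        mu, std = enc.encode(Tensor(rng.normal(size=(7, n))),
                             Tensor(np.zeros((n, n))))
        assert mu.shape == (7, n) and std.shape == (7, n)
        assert np.all(std.data > 0)


class TestVariationalPlumbing:
    def test_zero_input_zero_bias(self):
        head = (Tensor(np.ones((3, 2))), Tensor(np.zeros(2)))
        lat = gene_variational_head(np.zeros((4, 3)), head, head)
        np.testing.assert_array_equal(lat.mean, 0.0)
        np.testing.assert_allclose(lat.std, np.log(2.0))  # softplus(0)

    def test_std_stays_positive_for_very_negative_bias(self):
        head_mu = (Tensor(np.ones((2, 2))), Tensor(np.zeros(2)))
        head_sig = (Tensor(np.zeros((2, 2))), Tensor(np.full(2, -40.0)))
        lat = gene_variational_head(np.ones((3, 2)), head_mu, head_sig)
        assert np.all(lat.std > 0)

    def test_identity_head_passes_mean_through(self):
        head_mu = (Tensor(np.eye(1)), Tensor(np.zeros(1)))
        head_sig = (Tensor(np.zeros((1, 1))), Tensor(np.zeros(1)))
        x = np.array([[2.5], [-1.0]])
        np.testing.assert_allclose(
            gene_variational_head(x, head_mu, head_sig).mean, x)

    def test_reparameterize_sigma_zero_returns_mean(self):
        lat = GaussianLatent(np.arange(6.0).reshape(2, 3),
                             np.full((2, 3), 1e-300))
        z = reparameterize(lat, np.random.default_rng(0))
        np.testing.assert_allclose(z, lat.mean, atol=1e-250)

    def test_reparameterize_deterministic_given_seed(self):
        lat = GaussianLatent(np.zeros((3, 2)), np.ones((3, 2)))
        z1 = reparameterize(lat, np.random.default_rng(9))
        z2 = reparameterize(lat, np.random.default_rng(9))
        np.testing.assert_array_equal(z1, z2)

    def test_sample_mean_approaches_mu(self):
        mu, sigma = 1.5, 2.0
        lat = GaussianLatent(np.full((100_000, 1), mu),
                             np.full((100_000, 1), sigma))
        z = reparameterize(lat, np.random.default_rng(3))
        assert abs(z.mean() - mu) < 4 * sigma / np.sqrt(100_000)
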