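"""Expression normalization and the GCN autoencoder."""

import numpy as np
import pytest
from scipy import sparse

from spallm import (
    EncoderConfig,
    ExpressionMatrix,
    ValidationError,
    build_graph,
    gcn_layer,
    normalize_expression,
    train_spatial_encoder,
)


def em(values, **kw):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(values, [f"s{i}" for i in range(n)],
                            [f"g{j}" for j in range(m)], **kw)


class TestNormalizeExpression:
    def test_uniform_libraries_reduce_to_log1p(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])  # equal row sums
        out = normalize_expression(em(X), n_hvg=2)
        np.testing.assert_allclose(out.values, np.log1p(X), atol=1e-12)

    def test_library_scaling_to_median(self):
        X = np.array([[2.0, 0.0], [0.0, 4.0], [8.0, 0.0]])  # libraries 2,4,8
        out = normalize_expression(em(X), n_hvg=2)
        np.testing.assert_allclose(out.values[0, 0], np.log1p(4.0), atol=1e-12)
        np.testing.assert_allclose(out.values[2, 0], np.log1p(4.0), atol=1e-12)

    def test_all_zero_gene_excluded_when_selecting(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 10, (10, 5)).astype(float)
        X[:, 2] = 0.0
        out = normalize_expression(em(X), n_hvg=4)
        assert "g2" not in out.gene_symbols

    def test_hand_computed_dispersion_selects_top_gene(self):
        # equal libraries so scaling is identity; gene 3 has the largest
        # variance/mean of the scaled counts
        X = np.array(
            [[2.0, 1.0, 3.0, 0.0, 4.0],
             [2.0, 1.0, 3.0, 0.0, 4.0],
             [2.0, 1.0, 3.0, 10.0, 0.0],
             [2.0, 1.0, 3.0, 0.0, 4.0]]
        )
        mu = X.mean(0)
        disp = np.where(mu > 0, X.var(0) / np.where(mu > 0, mu, 1), 0)
        assert disp.argmax() == 3
        out = normalize_expression(em(X), n_hvg=2)
        assert "g3" in out.gene_symbols

    def test_idempotent_once_normalized(self):
        out = normalize_expression(em([[1.0, 2.0], [3.0, 4.0]]), n_hvg=2)
        again = normalize_expression(out, n_hvg=2)
        np.testing.assert_array_equal(again.values, out.values)

    def test_small_n_hvg_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(em([[1.0, 2.0]]), n_hvg=1)


def brute_gcn(H, A, W, act):
    n, d_in = H.shape
    d_out = W.shape[1]
    S = np.zeros((n, d_in))
    for i in range(n):
        for k in range(n):
            for j in range(d_in):
                S[i, j] += A[i, k] * H[k, j]
    Z = np.zeros((n, d_out))
    for i in range(n):
        for j in range(d_out):
            for k in range(d_in):
                Z[i, j] += S[i, k] * W[k, j]
    if act == "relu":
        return np.maximum(Z, 0)
    if act == "elu":
        return np.where(Z > 0, Z, np.expm1(Z))
    return Z


class TestGcnLayer:
    def test_identity_operators_pass_input_through(self):
        H = np.random.default_rng(0).standard_normal((4, 3))
        out = gcn_layer(H, sparse.eye(4, format="csr"), np.eye(3), "identity")
        np.testing.assert_allclose(out, H, atol=1e-12)

    @pytest.mark.parametrize("act", ["relu", "elu"])
    def test_zero_weights_give_zero_output(self, act):
        H = np.ones((3, 2))
        out = gcn_layer(H, sparse.eye(3, format="csr"), np.zeros((2, 2)), act)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("act", ["identity", "relu", "elu"])
    def test_matches_scalar_loop_oracle(self, act):
        rng = np.random.default_rng(42)
        for n, d_in, d_out in [(2, 2, 2), (5, 3, 4), (8, 6, 2)]:
            H = rng.standard_normal((n, d_in))
            A = rng.standard_normal((n, n))
            W = rng.standard_normal((d_in, d_out))
            got = gcn_layer(H, sparse.csr_matrix(A), W, act)
            np.testing.assert_allclose(got, brute_gcn(H, A, W, act), atol=1e-10)

    def test_shape_mismatch_reports_all_three(self):
        with pytest.raises(ValidationError, match=r"A_hat.*H.*W"):
            gcn_layer(np.ones((3, 2)), sparse.eye(4, format="csr"), np.ones((2, 2)))

    def test_single_layer_forward_is_permutation_equivariant(self):
        rng = np.random.default_rng(1)
        n = 12
        H = rng.standard_normal((n, 5))
        A = rng.uniform(0, 1, (n, n))
        A = (A + A.T) / 2
        W = rng.standard_normal((5, 3))
        perm = rng.permutation(n)
        out = gcn_layer(H, sparse.csr_matrix(A), W, "elu")
        out_p = gcn_layer(H[perm], sparse.csr_matrix(A[np.ix_(perm, perm)]), W, "elu")
        np.testing.assert_allclose(out[perm], out_p, atol=1e-10)


@pytest.fixture(scope="module")
def setup(small_tissue):
    X = normalize_expression(small_tissue.expression, n_hvg=60)
    graph = build_graph(small_tissue.coords)
    return X, graph.A_hat


class TestTraining:
    def test_same_seed_reproduces_embedding_bitwise(self, setup):
        X, A_hat = setup
        cfg = EncoderConfig(epochs=15, d_hidden=16, d_ST=8, seed=5)
        H1, t1 = train_spatial_encoder(X, A_hat, cfg)
        H2, t2 = train_spatial_encoder(X, A_hat, cfg)
        np.testing.assert_array_equal(H1.matrix, H2.matrix)
        assert t1.losses == t2.losses

    def test_loss_decreases_on_structured_data(self, setup):
        X, A_hat = setup
        _, trace = train_spatial_encoder(
            X, A_hat, EncoderConfig(epochs=60, d_hidden=16, d_ST=8, seed=0)
        )
        assert trace.losses[-1] < trace.losses[0]
        assert len(trace.losses) == 60

    def test_embedding_width_is_d_st(self, setup):
        X, A_hat = setup
        H, _ = train_spatial_encoder(
            X, A_hat, EncoderConfig(epochs=5, d_hidden=16, d_ST=32, seed=0)
        )
        assert H.matrix.shape == (X.n_spots, 32)
        assert H.stream == "spatial"

    def test_kmeans_on_spatial_embedding_recovers_domains(self, small_tissue):
        """With well-separated domain programs the latent space is clusterable."""
        from spallm import ClusterConfig, adjusted_rand_index, cluster

        X = normalize_expression(small_tissue.expression, n_hvg=60)
        A_hat = build_graph(small_tissue.coords).A_hat
        aris = []
        for seed in range(5):
            H, _ = train_spatial_encoder(
                X, A_hat, EncoderConfig(epochs=60, d_hidden=32, d_ST=16, seed=seed)
            )
            lab = cluster(H, ClusterConfig(n_clusters=5, seed=seed))
            aris.append(adjusted_rand_index(lab, small_tissue.truth))
        assert float(np.median(aris)) >= 0.8
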