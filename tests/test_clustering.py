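"""Clustering methods and the adjusted Rand index against a pair oracle."""

import itertools

import numpy as np
import pytest

from spallm import (
    ClusterConfig,
    DomainLabels,
    SpotEmbedding,
    ValidationError,
    adjusted_rand_index,
    cluster,
)


def ari_pair_oracle(a, b):
    """ARI by explicit enumeration of all n(n-1)/2 item pairs."""
    n = len(a)
    together_a = together_b = together_both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    total = n * (n - 1) // 2
    expected = together_a * together_b / total
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def set_partitions(n):
    """All set partitions of range(n) as restricted-growth label vectors."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([0], 0)


class TestARI:
    def test_identical_partitions_give_exactly_one(self):
        lab = DomainLabels(np.array([0, 0, 1, 2, 2, 1]))
        assert adjusted_rand_index(lab, lab) == 1.0

    def test_label_permutation_invariance(self):
        a = DomainLabels(np.array([0, 0, 1, 1]))
        b = DomainLabels(np.array([1, 1, 0, 0]))
        assert adjusted_rand_index(a, b) == 1.0

    def test_hand_enumerated_example(self):
        pred = DomainLabels(np.array([0, 0, 1, 1]))
        truth = DomainLabels(np.array([0, 0, 1, 2]))
        assert adjusted_rand_index(pred, truth) == pytest.approx(4 / 7)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = DomainLabels(rng.integers(0, 4, 30))
            b = DomainLabels(rng.integers(0, 3, 30))
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_index(b, a), abs=1e-12
            )

    def test_exhaustive_pair_oracle_small_n(self):
        """All pairs of set partitions of up to 5 items match the oracle."""
        for n in (3, 4, 5):
            parts = list(set_partitions(n))
            for pa in parts:
                for pb in parts:
                    got = adjusted_rand_index(DomainLabels(np.array(pa)),
                                              DomainLabels(np.array(pb)))
                    assert got == pytest.approx(ari_pair_oracle(pa, pb), abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 5, 40)
            b = rng.integers(0, 4, 40)
            assert adjusted_rand_index(
                DomainLabels(a), DomainLabels(b)
            ) == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_random_partitions_have_near_zero_mean(self):
        rng = np.random.default_rng(2)
        fixed = DomainLabels(np.repeat(np.arange(4), 50))
        vals = [
            adjusted_rand_index(fixed, DomainLabels(rng.integers(0, 4, 200)))
            for _ in range(1000)
        ]
        assert abs(float(np.mean(vals))) < 0.01

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index(DomainLabels(np.array([0, 1])),
                                DomainLabels(np.array([0, 1, 2])))


def blobs(seed, n_per=40, sep=20.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per, 2)),
                   rng.standard_normal((n_per, 2)) + sep])
    truth = DomainLabels(np.repeat([0, 1], n_per))
    return SpotEmbedding(X, "fused"), truth


class TestCluster:
    def test_kmeans_recovers_separated_blobs(self):
        Z, truth = blobs(0)
        lab = cluster(Z, ClusterConfig(method="kmeans", n_clusters=2, seed=0))
        assert adjusted_rand_index(lab, truth) == 1.0

    def test_k1_assigns_all_to_one_domain(self):
        Z, _ = blobs(1)
        lab = cluster(Z, ClusterConfig(n_clusters=1, seed=0))
        assert set(lab.labels.tolist()) == {0}

    @pytest.mark.parametrize("method", ["kmeans", "gmm", "louvain"])
    def test_seeded_determinism(self, method):
        Z, _ = blobs(2)
        cfg = ClusterConfig(method=method, n_clusters=2, seed=7)
        np.testing.assert_array_equal(cluster(Z, cfg).labels, cluster(Z, cfg).labels)

    def test_gmm_recovers_mixture_components(self):
        aris = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], 60),
                           rng.multivariate_normal([8, 8], [[1, -0.2], [-0.2, 1]], 60)])
            truth = DomainLabels(np.repeat([0, 1], 60))
            lab = cluster(SpotEmbedding(X, "fused"),
                          ClusterConfig(method="gmm", n_clusters=2, seed=seed))
            aris.append(adjusted_rand_index(lab, truth))
        assert float(np.median(aris)) >= 0.95

    def test_louvain_communities_refine_separated_blobs(self):
        # with widely separated blobs the kNN graph has no cross-blob edges,
        # so every modularity community lies entirely within one blob
        Z, truth = blobs(3, n_per=60)
        lab = cluster(Z, ClusterConfig(method="louvain", seed=0))
        assert lab.K >= 2
        for c in range(lab.K):
            assert len(set(truth.labels[lab.labels == c].tolist())) == 1

    def test_too_many_clusters_rejected(self):
        Z = SpotEmbedding(np.zeros((3, 2)), "fused")
        with pytest.raises(ValidationError):
            cluster(Z, ClusterConfig(n_clusters=5))


class TestBenchmark:
    def test_grid_shape_and_single_run_std(self, small_tissue, small_table, fast_encoder):
        from spallm import benchmark

        report = benchmark(small_tissue, small_table, levels=["Q0", "Q4"],
                           encoder_cfg=fast_encoder, n_runs=1, seed=0)
        assert len(report.rows) == 4 * 2  # strategies x levels
        assert all(r.std_ari == 0.0 for r in report.rows)
        assert all(r.n_runs == 1 for r in report.rows)
        df = report.to_dataframe()
        assert set(df.columns) == {"strategy", "level", "mean_ari", "std_ari", "n_runs"}
        assert "Q0" in report.format_table()

    def test_requires_truth_labels(self, small_tissue, small_table):
        from dataclasses import replace

        from spallm import benchmark

        no_truth = replace(small_tissue, truth=None)
        with pytest.raises(ValidationError, match="truth"):
            benchmark(no_truth, small_table, n_runs=1)
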