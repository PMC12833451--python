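"""Clustering of fused embeddings and adjusted-Rand-index evaluation.

The adjusted Rand index (ARI) is the chance-corrected pair-counting agreement
between two partitions, ``(RI - E[RI]) / (max(RI) - E[RI])``: 1 for identical
partitions, approximately 0 for random assignments.  It is computed here from
the contingency table of the two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DomainLabels, SpotEmbedding, ValidationError


@dataclass
class ClusterConfig:
    """Clustering algorithm choice and its settings.

    ``method`` is one of ``kmeans``, ``gmm`` (full-covariance Gaussian
    mixture, the mclust analogue) or ``louvain`` (modularity maximization on
    a 15-nearest-neighbor similarity graph built on the embedding).
    """

    method: str = "kmeans"
    n_clusters: int | None = None
    resolution: float = 1.0
    n_init: int = 10
    seed: int = 0
    knn: int = 15

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "gmm", "louvain"):
            raise ValidationError(f"unknown clustering method {self.method!r}")
        if self.method in ("kmeans", "gmm"):
            if self.n_clusters is None or self.n_clusters < 1:
                raise ValidationError(f"{self.method} requires n_clusters >= 1")


def _relabel_dense(labels: np.ndarray) -> DomainLabels:
    """Map arbitrary integer labels onto 0..K-1 by first appearance."""
    _, dense = np.unique(labels, return_inverse=True)
    return DomainLabels(dense)


def cluster(Z: SpotEmbedding, config: ClusterConfig) -> DomainLabels:
    """Partition the rows of ``Z`` into spatial domains."""
    X = Z.matrix
    n = X.shape[0]
    if config.method in ("kmeans", "gmm") and config.n_clusters > n:
        raise ValidationError(
            f"n_clusters={config.n_clusters} exceeds {n} spots"
        )
    if config.method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=config.n_clusters,
            n_init=config.n_init,
            random_state=config.seed,
        )
        return _relabel_dense(km.fit_predict(X))
    if config.method == "gmm":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=config.n_clusters,
            covariance_type="full",
            n_init=config.n_init,
            random_state=config.seed,
        )
        return _relabel_dense(gm.fit_predict(X))
    # louvain: modularity on a kNN similarity graph
    import random as _random

    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    k = min(config.knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for d, j in zip(dists[i, 1:], idx[i, 1:]):
            key = (min(i, int(j)), max(i, int(j)))
            edges[key] = max(edges.get(key, 0.0), 1.0 / (1.0 + float(d)))
    g = ig.Graph(n=n, edges=list(edges.keys()))
    weights = list(edges.values())
    _random.seed(config.seed)
    part = g.community_multilevel(weights=weights, resolution=config.resolution)
    return _relabel_dense(np.array(part.membership))


def adjusted_rand_index(pred: DomainLabels, truth: DomainLabels) -> float:
    """ARI between two partitions via the pair-counting contingency table."""
    a = pred.labels
    b = truth.labels
    if a.size != b.size:
        raise ValidationError(f"partition lengths differ: {a.size} vs {b.size}")
    n = a.size
    if n < 2:
        raise ValidationError("ARI needs at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x: np.ndarray) -> np.ndarray:
        return x * (x - 1) // 2

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(np.array(n)).item()
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions degenerate (all singletons / one cluster)
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

#: Integration strategies evaluated by the benchmark, as (name, alpha, beta);
#: "concatenation" is handled specially (standardized column stacking).
STRATEGIES = ("expression_only", "functional_only", "concatenation", "weighted")


@dataclass
class BenchmarkRow:
    strategy: str
    level: str
    mean_ari: float
    std_ari: float
    n_runs: int


@dataclass
class BenchmarkReport:
    """Strategy x quality-level grid of ARI summaries (mean +/- std over runs)."""

    rows: list[BenchmarkRow] = field(default_factory=list)

    def get(self, strategy: str, level: str) -> BenchmarkRow:
        for r in self.rows:
            if r.strategy == strategy and r.level == level:
                return r
        raise KeyError((strategy, level))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "level": r.level,
                    "mean_ari": r.mean_ari,
                    "std_ari": r.std_ari,
                    "n_runs": r.n_runs,
                }
                for r in self.rows
            ]
        )

    def format_table(self) -> str:
        """Text table: strategies as rows, quality levels as columns."""
        levels = sorted({r.level for r in self.rows})
        strategies = list(dict.fromkeys(r.strategy for r in self.rows))
        width = max(len(s) for s in strategies) + 2
        lines = ["Strategy".ljust(width) + "".join(lv.center(13) for lv in levels)]
        for s in strategies:
            cells = []
            for lv in levels:
                r = self.get(s, lv)
                cells.append(f"{r.mean_ari:.3f}±{r.std_ari:.3f}".center(13))
            lines.append(s.ljust(width) + "".join(cells))
        return "\n".join(lines)


def benchmark(
    dataset,
    table,
    levels: list[str] | None = None,
    encoder_cfg=None,
    cluster_cfg: ClusterConfig | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
    n_runs: int = 10,
    seed: int = 0,
    n_hvg: int = 3000,
) -> BenchmarkReport:
    """Quality-degradation benchmark over integration strategies.

    For each quality level the raw counts are masked once (level-specific
    seed held fixed across runs, so run-to-run variance reflects encoder and
    clustering initialization, not the mask) and the pipeline is repeated
    ``n_runs`` times with derived seeds.  All strategies share each run's
    encoder training, since they differ only downstream of the two streams.
    """
    from dataclasses import replace

    from .encoder import EncoderConfig
    from .fusion import FusionConfig, compute_streams, concatenate_streams, fuse
    from .quality import QUALITY_LEVELS, quality_grid
    from .types import Dataset

    if dataset.truth is None:
        raise ValidationError("benchmark requires ground-truth domain labels")
    levels = levels or list(QUALITY_LEVELS)
    encoder_cfg = encoder_cfg or EncoderConfig()
    cluster_cfg = cluster_cfg or ClusterConfig(n_clusters=dataset.truth.K)

    ss = np.random.SeedSequence(seed)
    mask_seed, run_root = (int(s) for s in ss.generate_state(2) % (2**31))
    grid = quality_grid(dataset.expression, seed=mask_seed)
    run_seeds = np.random.SeedSequence(run_root).generate_state(2 * n_runs) % (2**31)

    scores: dict[tuple[str, str], list[float]] = {
        (s, lv): [] for s in strategies for lv in levels
    }
    for level in levels:
        masked = Dataset(
            expression=grid[level], coords=dataset.coords, truth=dataset.truth,
            name=f"{dataset.name}:{level}",
        )
        for r in range(n_runs):
            enc_seed = int(run_seeds[2 * r])
            clu_seed = int(run_seeds[2 * r + 1])
            enc = replace(encoder_cfg, seed=enc_seed)
            clu = replace(cluster_cfg, seed=clu_seed)
            H_ST, H_PCA, _ = compute_streams(masked, table, enc, n_hvg=n_hvg)
            for strat in strategies:
                Z = _strategy_embedding(strat, H_ST, H_PCA)
                labels = cluster(Z, clu)
                scores[(strat, level)].append(
                    adjusted_rand_index(labels, dataset.truth)
                )

    report = BenchmarkReport()
    for strat in strategies:
        for level in levels:
            vals = np.array(scores[(strat, level)])
            report.rows.append(
                BenchmarkRow(
                    strategy=strat,
                    level=level,
                    mean_ari=float(vals.mean()),
                    std_ari=float(vals.std()),
                    n_runs=len(vals),
                )
            )
    return report


def _strategy_embedding(strategy: str, H_ST, H_PCA) -> SpotEmbedding:
    from .fusion import FusionConfig, concatenate_streams, fuse, standardize_stream

    if strategy == "expression_only":
        return SpotEmbedding(standardize_stream(H_ST).matrix, stream="fused")
    if strategy == "functional_only":
        return SpotEmbedding(standardize_stream(H_PCA).matrix, stream="fused")
    if strategy == "concatenation":
        return concatenate_streams(H_ST, H_PCA)
    if strategy == "weighted":
        return fuse(H_ST, H_PCA, FusionConfig(alpha=0.5, beta=0.5))
    raise ValidationError(f"unknown strategy {strategy!r}")
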