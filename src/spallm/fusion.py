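"""Functional encoding, stream calibration, weighted fusion, and the driver.

The functional stream is the matrix product ``H_LLM = X @ F`` of expression
with per-gene description-embedding vectors: each spot inherits a weighted
sum of the functional vectors of the genes it expresses.  After PCA-aligning
that stream to the spatial-embedding width, the fused representation is

    Z = alpha * H_ST + beta * H_LLM_PCA

computed by default on column-standardized streams, since the raw scales of a
trained latent embedding and an expression-weighted vector sum differ by
orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .clustering import ClusterConfig, cluster
from .encoder import EncoderConfig, normalize_expression, train_spatial_encoder
from .gene_features import align_genes, apply_pca, fit_pca
from .spatial_graph import build_graph
from .types import (
    Dataset,
    DomainLabels,
    ExpressionMatrix,
    GeneEmbeddingTable,
    SpotEmbedding,
    ValidationError,
)


@dataclass
class FusionConfig:
    """Weights and calibration for combining the two embedding streams."""

    alpha: float = 0.5
    beta: float = 0.5
    standardize: bool = True
    functional_source: str = "normalized"  # {"raw", "normalized"}

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("fusion weights must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValidationError("alpha + beta must be positive")
        if self.functional_source not in ("raw", "normalized"):
            raise ValidationError(
                f"functional_source must be 'raw' or 'normalized', got "
                f"{self.functional_source!r}"
            )


def functional_embed(X: ExpressionMatrix, F: np.ndarray) -> SpotEmbedding:
    """Functional spot embeddings ``H_LLM = X @ F``.

    ``X`` must already be restricted to the aligned genes, in the same order
    as the rows of ``F``.
    """
    F = np.asarray(F, dtype=np.float64)
    if X.n_genes != F.shape[0]:
        raise ValidationError(
            f"expression has {X.n_genes} genes but F has {F.shape[0]} rows"
        )
    return SpotEmbedding(matrix=X.values @ F, stream="functional")


def standardize_stream(H: SpotEmbedding) -> SpotEmbedding:
    """Column-wise zero-mean unit-variance calibration (population convention).

    Constant columns are mapped to zero.
    """
    if H.n_spots < 2:
        raise ValidationError("standardization needs at least 2 spots")
    X = H.matrix
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # divisor n
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return SpotEmbedding(matrix=out, stream=H.stream)


def fuse(H_ST: SpotEmbedding, H_LLM_PCA: SpotEmbedding, config: FusionConfig | None = None
         ) -> SpotEmbedding:
    """Weighted combination ``Z = alpha*H_ST + beta*H_LLM_PCA``.

    With a zero weight the corresponding stream is skipped entirely, so
    ``(alpha, beta) = (1, 0)`` returns the (standardized) spatial stream
    bit-for-bit.
    """
    config = config or FusionConfig()
    if H_ST.dim != H_LLM_PCA.dim:
        raise ValidationError(
            f"stream widths differ ({H_ST.dim} vs {H_LLM_PCA.dim}); "
            "apply_pca the functional stream to d_ST first"
        )
    if H_ST.n_spots != H_LLM_PCA.n_spots:
        raise ValidationError("streams disagree on spot count")
    A = standardize_stream(H_ST).matrix if config.standardize else H_ST.matrix
    B = standardize_stream(H_LLM_PCA).matrix if config.standardize else H_LLM_PCA.matrix
    if config.beta == 0:
        Z = A if config.alpha == 1.0 else config.alpha * A
    elif config.alpha == 0:
        Z = B if config.beta == 1.0 else config.beta * B
    else:
        Z = config.alpha * A + config.beta * B
    return SpotEmbedding(matrix=Z, stream="fused")


def concatenate_streams(H_ST: SpotEmbedding, H_LLM_PCA: SpotEmbedding) -> SpotEmbedding:
    """Column-standardized concatenation baseline (width ``2 * d_ST``)."""
    A = standardize_stream(H_ST).matrix
    B = standardize_stream(H_LLM_PCA).matrix
    return SpotEmbedding(matrix=np.hstack([A, B]), stream="fused")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Split one top-level seed into n independent stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class RunResult:
    """Outputs of one end-to-end pipeline run."""

    Z: SpotEmbedding
    labels: DomainLabels
    H_ST: SpotEmbedding
    H_LLM_PCA: SpotEmbedding | None
    report: dict[str, Any] = field(default_factory=dict)


def compute_streams(
    dataset: Dataset,
    table: GeneEmbeddingTable | None,
    encoder_cfg: EncoderConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    n_hvg: int = 3000,
    sigma: float | None = None,
    tau: float | None = None,
    k_neighbors: int = 6,
) -> tuple[SpotEmbedding, SpotEmbedding | None, dict[str, Any]]:
    """Compute the spatial and (when a table is given) functional streams.

    Shared by the driver and the benchmark harness so that strategies that
    differ only in fusion weights reuse one encoder training run.
    """
    encoder_cfg = encoder_cfg or EncoderConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    report: dict[str, Any] = {}

    X_norm = normalize_expression(dataset.expression, n_hvg=n_hvg)
    graph = build_graph(dataset.coords, sigma=sigma, tau=tau, k_neighbors=k_neighbors)
    report["sigma"] = graph.sigma
    report["tau"] = graph.tau
    report["n_hvg_used"] = X_norm.n_genes

    H_ST, trace = train_spatial_encoder(X_norm, graph.A_hat, encoder_cfg)
    report["encoder_seed"] = encoder_cfg.seed
    report["final_loss"] = trace.losses[-1]
    report["dims"] = {"X_norm": list(X_norm.values.shape), "H_ST": list(H_ST.matrix.shape)}

    H_LLM_PCA = None
    if table is not None:
        source = X_norm if fusion_cfg.functional_source == "normalized" else dataset.expression
        alignment = align_genes(source, table, missing_policy="drop")
        X_aligned = source.restrict_genes(alignment.kept_gene_indices)
        H_LLM = functional_embed(X_aligned, alignment.F_matrix)
        d_out = min(encoder_cfg.d_ST, H_LLM.n_spots, H_LLM.dim)
        pca = fit_pca(H_LLM, d_out=d_out, seed=encoder_cfg.seed)
        H_LLM_PCA = apply_pca(pca, H_LLM)
        if d_out < encoder_cfg.d_ST:
            # narrow embedding table: pad with zero columns so the streams
            # share width d_ST (the padding is inert under standardization)
            pad = np.zeros((H_LLM_PCA.n_spots, encoder_cfg.d_ST - d_out))
            H_LLM_PCA = SpotEmbedding(
                np.hstack([H_LLM_PCA.matrix, pad]), stream="functional_pca"
            )
        report["dropped_genes"] = len(alignment.dropped_symbols)
        report["dims"]["H_LLM"] = list(H_LLM.matrix.shape)
        report["dims"]["H_LLM_PCA"] = list(H_LLM_PCA.matrix.shape)
    return H_ST, H_LLM_PCA, report


def run_spallm(
    dataset: Dataset,
    table: GeneEmbeddingTable | None,
    encoder_cfg: EncoderConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    cluster_cfg: ClusterConfig | None = None,
    n_hvg: int = 3000,
    sigma: float | None = None,
    tau: float | None = None,
    k_neighbors: int = 6,
) -> RunResult:
    """End-to-end pipeline: normalize, embed both streams, fuse, cluster.

    With ``table=None`` or ``beta=0`` the functional stream is disabled and
    the result is the expression-only pipeline.
    """
    encoder_cfg = encoder_cfg or EncoderConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    if cluster_cfg is None:
        if dataset.truth is None:
            raise ValidationError(
                "cluster_cfg with n_clusters is required when the dataset has no truth labels"
            )
        cluster_cfg = ClusterConfig(n_clusters=dataset.truth.K)

    functional_active = table is not None and fusion_cfg.beta > 0
    H_ST, H_LLM_PCA, report = compute_streams(
        dataset,
        table if functional_active else None,
        encoder_cfg,
        fusion_cfg,
        n_hvg=n_hvg,
        sigma=sigma,
        tau=tau,
        k_neighbors=k_neighbors,
    )
    report["functional_stream"] = "enabled" if functional_active else "disabled"
    report["alpha"] = fusion_cfg.alpha
    report["beta"] = fusion_cfg.beta

    if functional_active:
        Z = fuse(H_ST, H_LLM_PCA, fusion_cfg)
    else:
        A = standardize_stream(H_ST).matrix if fusion_cfg.standardize else H_ST.matrix
        Z = SpotEmbedding(
            matrix=A if fusion_cfg.alpha == 1.0 else fusion_cfg.alpha * A, stream="fused"
        )
    labels = cluster(Z, cluster_cfg)
    report["K"] = labels.K
    report["dims"]["Z"] = list(Z.matrix.shape)
    return RunResult(Z=Z, labels=labels, H_ST=H_ST, H_LLM_PCA=H_LLM_PCA, report=report)
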