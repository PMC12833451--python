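"""Gene/table alignment and PCA reduction of the functional stream.

The functional stream multiplies the expression matrix by a per-gene
embedding table, so dataset genes must first be aligned with the table keys.
Symbols are matched case-insensitively after whitespace stripping, because
annotation tables and platform gene lists disagree on casing conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix, GeneEmbeddingTable, SpotEmbedding, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneAlignment:
    """Result of matching dataset genes against an embedding table.

    ``F_matrix`` rows correspond one-to-one (and in order) with
    ``kept_gene_indices`` into the expression matrix.
    """

    kept_gene_indices: np.ndarray
    F_matrix: np.ndarray
    dropped_symbols: list[str]


def align_genes(expr: ExpressionMatrix, table: GeneEmbeddingTable,
                missing_policy: str = "drop") -> GeneAlignment:
    """Match expression-matrix genes with embedding-table rows.

    ``missing_policy='drop'`` keeps exactly the genes present in the table
    (dataset order preserved); ``'zero'`` keeps all genes and assigns all-zero
    vectors to the absent ones.
    """
    if missing_policy not in ("drop", "zero"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    kept: list[int] = []
    rows: list[np.ndarray] = []
    dropped: list[str] = []
    zero = np.zeros(table.dim)
    for j, sym in enumerate(expr.gene_symbols):
        if sym in table:
            kept.append(j)
            rows.append(table.lookup(sym))
        else:
            dropped.append(sym)
            if missing_policy == "zero":
                kept.append(j)
                rows.append(zero)
    if not kept:
        raise ValidationError("no overlapping genes between expression matrix and table")
    if dropped:
        shown = ", ".join(dropped[:20])
        more = f" (+{len(dropped) - 20} more)" if len(dropped) > 20 else ""
        logger.warning("%d genes missing from the embedding table: %s%s",
                       len(dropped), shown, more)
    return GeneAlignment(
        kept_gene_indices=np.array(kept, dtype=int),
        F_matrix=np.vstack(rows),
        dropped_symbols=dropped,
    )


@dataclass
class PCAModel:
    """A fitted PCA: centering mean plus row-orthonormal components.

    Component signs follow the convention that the largest-magnitude loading
    of each component is positive, which makes the fit deterministic.
    """

    mean: np.ndarray
    components: np.ndarray          # (d_out, d_in), row-orthonormal
    explained_variance: np.ndarray  # non-increasing

    @property
    def d_in(self) -> int:
        return self.components.shape[1]

    @property
    def d_out(self) -> int:
        return self.components.shape[0]


# Above this many input columns a truncated randomized SVD is used; the exact
# full SVD is affordable (and exactly reproducible) everywhere below it.
_RANDOMIZED_SVD_THRESHOLD = 4096


def fit_pca(H: SpotEmbedding, d_out: int, seed: int = 0) -> PCAModel:
    """Fit a PCA of width ``d_out`` on the rows of ``H``.

    Uses a deterministic full SVD at the widths this package encounters
    (embedding tables up to 1536 columns); a seeded randomized solver is used
    only beyond ``_RANDOMIZED_SVD_THRESHOLD`` input columns.
    """
    X = H.matrix
    n, d_in = X.shape
    if d_out > min(n, d_in):
        raise ValidationError(
            f"d_out={d_out} exceeds min(n_spots={n}, d_in={d_in})"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    if d_in <= _RANDOMIZED_SVD_THRESHOLD:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    else:
        from sklearn.utils.extmath import randomized_svd

        _, s, Vt = randomized_svd(Xc, n_components=d_out, random_state=seed)
    comps = Vt[:d_out]
    # fix signs: largest-magnitude loading positive per component
    flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    ev = (s[:d_out] ** 2) / n
    return PCAModel(mean=mean, components=comps, explained_variance=ev)


def apply_pca(model: PCAModel, H: SpotEmbedding) -> SpotEmbedding:
    """Project ``H`` onto the fitted components (centered with the model mean)."""
    if H.dim != model.d_in:
        raise ValidationError(
            f"embedding width {H.dim} does not match PCA input width {model.d_in}"
        )
    Z = (H.matrix - model.mean) @ model.components.T
    return SpotEmbedding(matrix=Z, stream="functional_pca")
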