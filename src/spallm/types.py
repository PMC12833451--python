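"""Core data containers for the spatial-domain identification pipeline.

All containers are thin, validated wrappers around numpy arrays.  Spot order
is the single source of truth: every container derived from an
:class:`ExpressionMatrix` keeps its rows in the same order as that matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


def _canon(symbol: str) -> str:
    """Canonical gene-symbol key: whitespace-stripped, case-folded."""
    return symbol.strip().casefold()


@dataclass
class ExpressionMatrix:
    """A spots x genes non-negative expression matrix.

    Parameters
    ----------
    values
        Dense ``(n_spots, m_genes)`` array of counts or normalized values.
    spot_ids
        Unique spot/cell barcodes, one per row.
    gene_symbols
        Unique (after case-folding) gene symbols, one per column.
    is_normalized
        Whether :func:`spallm.encoder.normalize_expression` has been applied.
    """

    values: np.ndarray
    spot_ids: list[str]
    gene_symbols: list[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        if self.values.ndim != 2:
            raise ValidationError(f"expression matrix must be 2-D, got {self.values.ndim}-D")
        n, m = self.values.shape
        if len(self.spot_ids) != n:
            raise ValidationError(
                f"spot_ids length {len(self.spot_ids)} does not match {n} matrix rows"
            )
        if len(self.gene_symbols) != m:
            raise ValidationError(
                f"gene_symbols length {len(self.gene_symbols)} does not match {m} matrix columns"
            )
        if len(set(self.spot_ids)) != n:
            raise ValidationError("spot_ids are not unique")
        canon = [_canon(g) for g in self.gene_symbols]
        if len(set(canon)) != m:
            seen: set[str] = set()
            dups = sorted({c for c in canon if c in seen or seen.add(c)})
            raise ValidationError(f"gene symbols collide after case-folding: {dups[:20]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValidationError("expression matrix contains negative entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, indices: np.ndarray | list[int]) -> "ExpressionMatrix":
        """Column subset preserving spot order."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            spot_ids=list(self.spot_ids),
            gene_symbols=[self.gene_symbols[i] for i in idx],
            is_normalized=self.is_normalized,
        )


@dataclass
class SpatialCoords:
    """Planar coordinates of spots, in the same row order as the expression matrix."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(f"coordinates must be n x 2, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite entries")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass
class GeneEmbeddingTable:
    """Lookup table gene symbol -> fixed-width description-embedding vector.

    Keys are matched case-insensitively (whitespace-stripped); the original
    spelling of each symbol is preserved for output.
    """

    symbols: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = [str(s) for s in self.symbols]
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValidationError("embedding vectors must form a 2-D array")
        if len(self.symbols) != self.vectors.shape[0]:
            raise ValidationError(
                f"{len(self.symbols)} symbols but {self.vectors.shape[0]} vectors"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("embedding table contains non-finite entries")
        canon = [_canon(s) for s in self.symbols]
        if len(set(canon)) != len(canon):
            seen: set[str] = set()
            dups = sorted({c for c in canon if c in seen or seen.add(c)})
            raise ValidationError(f"duplicate symbols after case-folding: {dups[:20]}")
        self._index: dict[str, int] = {c: i for i, c in enumerate(canon)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, symbol: str) -> bool:
        return _canon(symbol) in self._index

    def lookup(self, symbol: str) -> np.ndarray:
        return self.vectors[self._index[_canon(symbol)]]


_STREAM_TAGS = ("spatial", "functional", "functional_pca", "fused")


@dataclass
class SpotEmbedding:
    """An ``(n_spots, d)`` latent representation of spots from one stream."""

    matrix: np.ndarray
    stream: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("embedding must be a 2-D matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("embedding contains non-finite entries")
        if self.stream not in _STREAM_TAGS:
            raise ValidationError(f"unknown stream tag {self.stream!r}; expected {_STREAM_TAGS}")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DomainLabels:
    """An integer partition of the spots into K spatial domains."""

    labels: np.ndarray
    K: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        if self.K == 0:
            self.K = int(self.labels.max()) + 1 if self.labels.size else 0
        if self.labels.size and self.labels.max() >= self.K:
            raise ValidationError(f"label {self.labels.max()} >= K={self.K}")

    @property
    def n_spots(self) -> int:
        return self.labels.shape[0]


@dataclass
class Dataset:
    """Expression, coordinates and (optionally) ground-truth domain labels."""

    expression: ExpressionMatrix
    coords: SpatialCoords
    truth: DomainLabels | None = None
    name: str = field(default="dataset")

    def __post_init__(self) -> None:
        if self.coords.n_spots != self.expression.n_spots:
            raise ValidationError(
                f"coords have {self.coords.n_spots} rows but expression has "
                f"{self.expression.n_spots} spots"
            )
        if self.truth is not None and self.truth.n_spots != self.expression.n_spots:
            raise ValidationError(
                f"truth labels have {self.truth.n_spots} entries but expression has "
                f"{self.expression.n_spots} spots"
            )

    @property
    def n_spots(self) -> int:
        return self.expression.n_spots
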