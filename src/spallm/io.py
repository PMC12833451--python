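"""Readers and writers for expression containers, embedding tables and labels.

Two on-disk layouts are supported for datasets:

* ``h5ad`` — an AnnData container with expression in ``X``, coordinates in
  ``obsm["spatial"]`` and an optional per-spot annotation column in ``obs``.
* ``mtx_dir`` — a directory with ``matrix.mtx`` (MatrixMarket), ``genes.tsv``,
  ``barcodes.tsv``, ``coords.tsv`` (two tab-separated columns, spot order) and
  an optional ``labels.tsv``.

Gene symbols are matched case-insensitively elsewhere in the package, but the
spellings found in the input files are preserved verbatim on output.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import (
    Dataset,
    DomainLabels,
    ExpressionMatrix,
    GeneEmbeddingTable,
    SpatialCoords,
    ValidationError,
)

ANNOTATION_COLUMN = "domain"


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def read_dataset(path: str | os.PathLike, format: str | None = None,
                 annotation_column: str = ANNOTATION_COLUMN) -> Dataset:
    """Read a dataset from an h5ad file or an MTX-triplet directory.

    ``format`` is inferred from the path when omitted (``.h5ad`` suffix vs
    directory).  Truth labels are attached when the designated annotation
    column (h5ad ``obs``) or a ``labels.tsv`` file (mtx_dir) is present.
    """
    path = Path(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "mtx_dir"
    if format == "h5ad":
        return _read_h5ad(_require(path), annotation_column)
    if format == "mtx_dir":
        return _read_mtx_dir(_require(path))
    raise ValidationError(f"unknown dataset format {format!r}; expected 'h5ad' or 'mtx_dir'")


def _labels_from_strings(raw: list[str]) -> DomainLabels:
    """Map arbitrary annotation values to dense integer codes (sorted order)."""
    cats = sorted(set(raw))
    code = {c: i for i, c in enumerate(cats)}
    return DomainLabels(np.array([code[v] for v in raw]), K=len(cats))


def _read_h5ad(path: Path, annotation_column: str) -> Dataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    expr = ExpressionMatrix(
        values=np.asarray(X, dtype=np.float64),
        spot_ids=list(map(str, adata.obs_names)),
        gene_symbols=list(map(str, adata.var_names)),
        is_normalized=bool(adata.uns.get("spallm_is_normalized", False)),
    )
    if "spatial" not in adata.obsm:
        raise ValidationError(f"{path}: no obsm['spatial'] coordinate slot")
    coords = SpatialCoords(np.asarray(adata.obsm["spatial"], dtype=np.float64))
    truth = None
    if annotation_column in adata.obs.columns:
        truth = _labels_from_strings([str(v) for v in adata.obs[annotation_column]])
    return Dataset(expression=expr, coords=coords, truth=truth, name=path.stem)


def _read_mtx_dir(path: Path) -> Dataset:
    mtx = _require(path / "matrix.mtx")
    genes_f = _require(path / "genes.tsv")
    barcodes_f = _require(path / "barcodes.tsv")
    coords_f = _require(path / "coords.tsv")

    M = spio.mmread(mtx)
    M = np.asarray(M.todense() if sparse.issparse(M) else M, dtype=np.float64)
    genes = genes_f.read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g.strip()]
    barcodes = [b.strip() for b in barcodes_f.read_text().splitlines() if b.strip()]

    # MTX orientation in the wild is either genes x spots or spots x genes;
    # disambiguate against the gene-list length.
    n_r, n_c = M.shape
    if n_c == len(genes) and n_r == len(barcodes):
        pass
    elif n_r == len(genes) and n_c == len(barcodes):
        M = M.T
    else:
        raise ValidationError(
            f"{mtx}: matrix shape {M.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )

    cf = pd.read_csv(coords_f, sep="\t", header=None)
    if cf.shape[1] < 2:
        raise ValidationError(f"{coords_f}: expected two tab-separated coordinate columns")
    coords = SpatialCoords(cf.iloc[:, :2].to_numpy(dtype=np.float64))

    truth = None
    labels_f = path / "labels.tsv"
    if labels_f.exists():
        raw = [v.strip() for v in labels_f.read_text().splitlines() if v.strip()]
        if len(raw) != len(barcodes):
            raise ValidationError(
                f"{labels_f}: {len(raw)} labels but {len(barcodes)} barcodes"
            )
        truth = _labels_from_strings(raw)

    expr = ExpressionMatrix(values=M, spot_ids=barcodes, gene_symbols=genes)
    return Dataset(expression=expr, coords=coords, truth=truth, name=path.name)


def write_dataset(dataset: Dataset, path: str | os.PathLike, format: str = "h5ad",
                  annotation_column: str = ANNOTATION_COLUMN) -> None:
    """Write a dataset as h5ad or as an MTX-triplet directory."""
    path = Path(path)
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=dataset.expression.values.copy(),
            obs=pd.DataFrame(index=pd.Index(dataset.expression.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(dataset.expression.gene_symbols, name="gene")),
        )
        adata.obsm["spatial"] = dataset.coords.coords.copy()
        adata.uns["spallm_is_normalized"] = bool(dataset.expression.is_normalized)
        if dataset.truth is not None:
            adata.obs[annotation_column] = [str(v) for v in dataset.truth.labels]
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(dataset.expression.values))
        (path / "genes.tsv").write_text("\n".join(dataset.expression.gene_symbols) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(dataset.expression.spot_ids) + "\n")
        np.savetxt(path / "coords.tsv", dataset.coords.coords, delimiter="\t", fmt="%.10g")
        if dataset.truth is not None:
            (path / "labels.tsv").write_text(
                "\n".join(str(v) for v in dataset.truth.labels) + "\n"
            )
    else:
        raise ValidationError(f"unknown dataset format {format!r}")


def read_gene_embedding_table(path: str | os.PathLike, key_column: str | int = 0,
                              dim_check: int | None = None) -> GeneEmbeddingTable:
    """Read a symbol-keyed embedding table from CSV/TSV.

    ``key_column`` names (or indexes) the symbol column; every other column
    must be numeric.  ``dim_check`` asserts the expected vector width.
    """
    path = _require(Path(path))
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(key_column, int):
        key_column = df.columns[key_column]
    if key_column not in df.columns:
        raise ValidationError(f"{path}: no column named {key_column!r}")
    symbols = [str(s) for s in df[key_column]]
    num = df.drop(columns=[key_column])
    for col in num.columns:
        coerced = pd.to_numeric(num[col], errors="coerce")
        if coerced.isna().any() and not num[col].isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise ValidationError(f"{path}: non-numeric cell in column {col!r}, row {row}")
        num[col] = coerced
    vectors = num.to_numpy(dtype=np.float64)
    table = GeneEmbeddingTable(symbols=symbols, vectors=vectors)
    if dim_check is not None and table.dim != dim_check:
        raise ValidationError(
            f"{path}: embedding width {table.dim} != expected {dim_check}"
        )
    return table


def write_gene_embedding_table(table: GeneEmbeddingTable, path: str | os.PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(table.vectors, columns=[f"e{i}" for i in range(table.dim)])
    df.insert(0, "gene", table.symbols)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def write_labels(labels: DomainLabels, spot_ids: list[str], path: str | os.PathLike) -> None:
    """Write predicted domains as a two-column CSV (spot_id, domain)."""
    if len(spot_ids) != labels.n_spots:
        raise ValidationError(
            f"{len(spot_ids)} spot ids but {labels.n_spots} labels"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"spot_id": list(spot_ids), "domain": labels.labels})
    df.to_csv(path, index=False)


def read_labels(path: str | os.PathLike) -> tuple[DomainLabels, list[str]]:
    """Read a labels CSV written by :func:`write_labels`."""
    df = pd.read_csv(_require(Path(path)))
    if not {"spot_id", "domain"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns spot_id, domain")
    labels = DomainLabels(df["domain"].to_numpy(dtype=np.int64))
    return labels, [str(s) for s in df["spot_id"]]
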