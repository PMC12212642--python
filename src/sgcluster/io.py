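"""Expression-matrix I/O and preprocessing.

The in-memory container is :class:`ExpressionMatrix` (cells in rows, genes
in columns, unique string identifiers).  Readers accept dense CSV/TSV,
Matrix Market triplets with gene/barcode companion files, and ``.h5ad``;
whatever the on-disk orientation, the result is cells x genes.

Preprocessing follows standard single-cell practice: drop genes expressed
in too few cells and cells expressing too few genes, scale each cell to the
median library size, log1p, and keep the most variable genes.  Filtering,
normalisation and log transform are delegated to scanpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "EmptyResultError",
    "PreprocessConfig",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "preprocess",
    "CountPreprocessor",
]


class ParseError(ValueError):
    """Malformed input file (ragged rows, negative entries, duplicate ids...)."""


class EmptyResultError(ValueError):
    """All cells or all genes were removed by filtering."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    ``is_counts`` distinguishes raw integer counts from transformed values;
    preprocessing only normalises/logs count data.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    is_counts: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ParseError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ParseError("identifier lists must match the matrix shape")
        if not np.isfinite(self.values).all():
            raise ParseError("expression values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative expression value at cell '{self.cell_ids[i]}', "
                f"gene '{self.gene_ids[j]}'"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise ParseError(f"duplicate {name} identifier: '{dup}'")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )

    @classmethod
    def from_anndata(cls, adata, is_counts: bool = True) -> "ExpressionMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(np.asarray(X, dtype=np.float64),
                   list(map(str, adata.obs_names)),
                   list(map(str, adata.var_names)), is_counts=is_counts)


# ---------------------------------------------------------------------- readers

def _read_dense(path: Path, sep: str, cells_in_rows: bool) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pandas raises a zoo of error types
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{path} contains missing values or ragged rows")
    if not cells_in_rows:
        df = df.T
    vals = df.to_numpy(dtype=np.float64)
    is_counts = bool(np.array_equal(vals, np.round(vals)))
    return ExpressionMatrix(vals, list(df.index.astype(str)),
                            list(df.columns.astype(str)), is_counts=is_counts)


def _companion(path: Path, names: tuple[str, ...]) -> Path | None:
    for name in names:
        cand = path.parent / name
        if cand.exists():
            return cand
    return None


def _read_mtx(path: Path, cells_in_rows: bool) -> ExpressionMatrix:
    from scipy.io import mmread

    try:
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path), dtype=np.float64)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    stem = path.stem
    genes_path = _companion(path, (f"{stem}_genes.tsv", "genes.tsv", "features.tsv"))
    cells_path = _companion(path, (f"{stem}_barcodes.tsv", "barcodes.tsv"))
    # Matrix Market convention here: genes in rows, cells in columns
    if not cells_in_rows:
        mat = mat.T
    n, m = mat.shape
    gene_ids = (pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
                if genes_path else [f"gene_{j}" for j in range(m)])
    cell_ids = (pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
                if cells_path else [f"cell_{i}" for i in range(n)])
    is_counts = bool(np.array_equal(mat, np.round(mat)))
    return ExpressionMatrix(mat, cell_ids, gene_ids, is_counts=is_counts)


def read_expression(path, format: str | None = None,
                    cells_in_rows: bool | None = None) -> ExpressionMatrix:
    """Read an expression matrix; orientation is normalised to cells x genes.

    ``cells_in_rows`` defaults to True for csv/tsv and False for mtx (the
    10x genes-in-rows convention).  ``format`` is inferred from the suffix
    when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx",
                  ".h5ad": "h5ad"}.get(path.suffix.lower())
        if format is None:
            raise ParseError(f"cannot infer format of {path}")
    format = format.lower()
    if format in ("csv", "tsv"):
        return _read_dense(path, "," if format == "csv" else "\t",
                           True if cells_in_rows is None else cells_in_rows)
    if format == "mtx":
        return _read_mtx(path, False if cells_in_rows is None else cells_in_rows)
    if format == "h5ad":
        import anndata as ad

        return ExpressionMatrix.from_anndata(ad.read_h5ad(path))
    raise ParseError(f"unknown format '{format}'")


def write_expression(em: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write csv/tsv (cells in rows) or mtx (genes in rows, with companions)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix.lower())
    if format in ("csv", "tsv"):
        vals = em.values
        if em.is_counts:
            vals = vals.astype(np.int64)
        df = pd.DataFrame(vals, index=em.cell_ids, columns=em.gene_ids)
        df.to_csv(path, sep="," if format == "csv" else "\t")
    elif format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        vals = em.values.T  # genes x cells on disk
        if em.is_counts:
            vals = vals.astype(np.int64)
        mmwrite(str(path), csr_matrix(vals))
        stem = path.stem
        pd.Series(em.gene_ids).to_csv(path.parent / f"{stem}_genes.tsv",
                                      sep="\t", header=False, index=False)
        pd.Series(em.cell_ids).to_csv(path.parent / f"{stem}_barcodes.tsv",
                                      sep="\t", header=False, index=False)
    else:
        raise ParseError(f"unsupported output format '{format}'")


def read_labels(path) -> pd.Series:
    """Two-column TSV (cell_id, label) -> Series indexed by cell id."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (cell_id, label)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values,
                     name="label")


def write_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------- preprocessing

@dataclass
class PreprocessConfig:
    min_cells: int = 3       # gene kept if expressed in >= min_cells cells
    min_genes: int = 200     # cell kept if it expresses >= min_genes genes
    n_hvg: int = 2000        # most variable genes retained (None/0 keeps all)
    target_sum: float | None = None  # None -> median library size


def preprocess(em: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """QC filter, median-library normalise, log1p, and keep top variable genes.

    Normalisation and log transform apply only to count input; transformed
    input passes through filtering and gene selection with a warning.
    """
    import scanpy as sc

    cfg = cfg or PreprocessConfig()
    adata = em.to_anndata()
    if cfg.min_cells > 0:
        sc.pp.filter_genes(adata, min_cells=cfg.min_cells)
    if cfg.min_genes > 0:
        sc.pp.filter_cells(adata, min_genes=cfg.min_genes)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise EmptyResultError(
            f"filtering removed everything ({adata.n_obs} cells, {adata.n_vars} genes left)"
        )
    if em.is_counts:
        target = cfg.target_sum
        if target is None:
            target = float(np.median(np.asarray(adata.X).sum(axis=1)))
        sc.pp.normalize_total(adata, target_sum=target)
        sc.pp.log1p(adata)
    else:
        warnings.warn("input is not raw counts; skipping normalisation and log1p",
                      RuntimeWarning, stacklevel=2)
    if cfg.n_hvg and cfg.n_hvg < adata.n_vars:
        var = np.asarray(adata.X).var(axis=0)
        # stable ranking: variance descending, original gene order breaks ties
        top = np.sort(np.argsort(-var, kind="stable")[: cfg.n_hvg])
        adata = adata[:, top].copy()
    return ExpressionMatrix.from_anndata(adata, is_counts=False)


class CountPreprocessor:
    """scikit-learn style transformer wrapping :func:`preprocess`.

    Operates on :class:`ExpressionMatrix` (or a raw array, in which case
    identifiers are synthesised).  Stateless between calls apart from the
    recorded gene selection of the last ``transform``.
    """

    def __init__(self, min_cells: int = 3, min_genes: int = 200,
                 n_hvg: int = 2000, target_sum: float | None = None):
        self.min_cells = min_cells
        self.min_genes = min_genes
        self.n_hvg = n_hvg
        self.target_sum = target_sum

    def get_params(self, deep: bool = True):
        return {"min_cells": self.min_cells, "min_genes": self.min_genes,
                "n_hvg": self.n_hvg, "target_sum": self.target_sum}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> ExpressionMatrix:
        if not isinstance(X, ExpressionMatrix):
            X = np.asarray(X, dtype=np.float64)
            X = ExpressionMatrix(
                X, [f"cell_{i}" for i in range(X.shape[0])],
                [f"gene_{j}" for j in range(X.shape[1])],
                is_counts=bool(np.array_equal(X, np.round(X))),
            )
        out = preprocess(X, PreprocessConfig(self.min_cells, self.min_genes,
                                             self.n_hvg, self.target_sum))
        self.gene_ids_ = list(out.gene_ids)
        self.cell_ids_ = list(out.cell_ids)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
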