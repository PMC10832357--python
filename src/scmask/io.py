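"""Reading expression matrices and the standard scRNA-seq preprocessing recipe.

Supported on-disk layouts: 10x-style MatrixMarket triplet directories
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``/``genes.tsv``, stored
genes x cells and transposed on load), delimited text with cells in rows and
a gene header, and AnnData ``.h5ad`` containers.

The preprocessing pipeline is the consensus recipe used throughout the
single-cell clustering literature: filter rarely expressed genes,
library-size normalize each cell, log1p, keep the most dispersed genes, and
standardize each gene with symmetric clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy.io import mmread, mmwrite

STAGES = ("raw_counts", "normalized", "scaled")


@dataclass
class ExpressionMatrix:
    """A dense cells x genes expression matrix with identifiers.

    ``stage`` tracks processing state: ``raw_counts`` (non-negative counts),
    ``normalized`` (library-size normalized + log1p) or ``scaled``
    (per-gene standardized, model-ready).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if sparse.issparse(self.values):  # pragma: no cover - coerced above
            self.values = self.values.toarray()
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        c, g = self.values.shape
        if c < 2 or g < 2:
            raise ValueError(f"need at least 2 cells and 2 genes, got {c}x{g}")
        if len(self.cell_ids) != c:
            raise ValueError(
                f"matrix has {c} cells but {len(self.cell_ids)} cell identifiers"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"matrix has {g} genes but {len(self.gene_ids)} gene identifiers"
            )
        if len(set(self.cell_ids)) != c:
            raise ValueError("cell identifiers are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene identifiers are not unique")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.stage == "raw_counts" and np.any(self.values < 0):
            raise ValueError("raw_counts stage requires non-negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(X=self.values.copy())
        adata.obs_names = list(self.cell_ids)
        adata.var_names = list(self.gene_ids)
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, stage: str = "raw_counts") -> "ExpressionMatrix":
        x = adata.X
        if sparse.issparse(x):
            x = x.toarray()
        return cls(
            values=np.asarray(x, dtype=np.float64),
            cell_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            stage=stage,
        )


def _read_delimited(path: Path) -> ExpressionMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        cell_ids=list(map(str, df.index)),
        gene_ids=list(map(str, df.columns)),
    )


def _find_triplet_file(directory: Path, candidates: Sequence[str]) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"none of {list(candidates)} found in triplet directory {directory}"
    )


def _read_mtx_dir(directory: Path) -> ExpressionMatrix:
    matrix_path = _find_triplet_file(directory, ["matrix.mtx", "matrix.mtx.gz"])
    barcodes_path = _find_triplet_file(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    features_path = _find_triplet_file(
        directory, ["features.tsv", "genes.tsv", "features.tsv.gz", "genes.tsv.gz"]
    )
    mat = mmread(str(matrix_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64).T  # stored genes x cells
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix in {directory} is {mat.shape[0]}x{mat.shape[1]} after transpose "
            f"but annotations give {len(barcodes)} barcodes x {len(features)} features"
        )
    return ExpressionMatrix(values=mat, cell_ids=barcodes, gene_ids=features)


def load_matrix(path: str | Path, format: str) -> ExpressionMatrix:
    """Read an expression matrix into a cells x genes ``ExpressionMatrix``.

    Parameters
    ----------
    path
        File (``delimited``, ``h5ad``) or directory (``mtx_dir``).
    format
        One of ``mtx_dir``, ``delimited``, ``h5ad``. Triplet directories are
        stored genes x cells and are transposed on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format == "delimited":
        return _read_delimited(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"mtx_dir format expects a directory: {path}")
        return _read_mtx_dir(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        return ExpressionMatrix.from_anndata(adata)
    raise ValueError(f"unknown format {format!r}; expected mtx_dir, delimited or h5ad")


def write_delimited(x: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(x.values, index=x.cell_ids, columns=x.gene_ids)
    df.to_csv(path, sep=sep)


def write_mtx_dir(x: ExpressionMatrix, directory: str | Path) -> None:
    """Write a 10x-style triplet directory (matrix stored genes x cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.csr_matrix(x.values.T))
    pd.Series(x.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    feats = pd.DataFrame({"id": x.gene_ids, "name": x.gene_ids, "type": "Gene Expression"})
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)


def write_h5ad(x: ExpressionMatrix, path: str | Path) -> None:
    x.to_anndata().write_h5ad(Path(path))


def library_normalize(x: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Per-cell library-size normalization to ``target_sum`` followed by log1p."""
    if x.stage != "raw_counts":
        raise ValueError(f"expected raw_counts input, got stage={x.stage!r}")
    totals = x.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        bad = [cid for cid, z in zip(x.cell_ids, zero) if z]
        raise ValueError(f"cells with zero total count cannot be normalized: {bad}")
    v = np.log1p(x.values * (target_sum / totals)[:, None])
    return replace(x, values=v, stage="normalized")


def select_hvg(x: ExpressionMatrix, n_hvg: int) -> ExpressionMatrix:
    """Keep the top ``n_hvg`` genes by dispersion-based ranking (log-space)."""
    if n_hvg > x.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds available genes ({x.n_genes})")
    if n_hvg == x.n_genes:
        return x
    adata = x.to_anndata()
    sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
    keep = np.flatnonzero(adata.var["highly_variable"].to_numpy())
    return replace(
        x,
        values=x.values[:, keep],
        gene_ids=[x.gene_ids[i] for i in keep],
    )


def standardize(x: ExpressionMatrix, clip: float = 10.0) -> ExpressionMatrix:
    """Per-gene zero mean / unit variance, clipped to [-clip, clip].

    Zero-variance genes map to an all-zero column rather than NaN.
    """
    mu = x.values.mean(axis=0)
    sd = x.values.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    v = np.clip((x.values - mu) / safe, -clip, clip)
    return replace(x, values=v, stage="scaled")


def preprocess(
    x: ExpressionMatrix,
    n_hvg: int = 2000,
    target_sum: float = 1e4,
    clip: float = 10.0,
    min_cells: int = 3,
) -> ExpressionMatrix:
    """Full preprocessing pipeline producing the model-ready matrix.

    Steps: (1) drop genes expressed in fewer than ``min_cells`` cells,
    (2) per-cell library-size normalization to ``target_sum``, (3) log1p,
    (4) top ``n_hvg`` genes by dispersion ranking, (5) per-gene
    standardization clipped to ``[-clip, clip]``. Deterministic.
    """
    if x.stage != "raw_counts":
        raise ValueError(f"preprocess expects raw_counts input, got {x.stage!r}")
    if min_cells > 0:
        expressed = (x.values > 0).sum(axis=0)
        keep = np.flatnonzero(expressed >= min_cells)
        if keep.size < 2:
            raise ValueError(f"fewer than 2 genes expressed in >= {min_cells} cells")
        x = replace(
            x,
            values=x.values[:, keep],
            gene_ids=[x.gene_ids[i] for i in keep],
        )
    if n_hvg > x.n_genes:
        raise ValueError(
            f"n_hvg={n_hvg} exceeds {x.n_genes} genes surviving the min_cells filter"
        )
    x = library_normalize(x, target_sum=target_sum)
    x = select_hvg(x, n_hvg)
    return standardize(x, clip=clip)
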