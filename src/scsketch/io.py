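"""Expression-matrix I/O and minimal preprocessing.

Matrices are held dense (cells x genes) with string identifiers on both
axes and a ``layer`` tag recording what transformation has been applied:
``raw`` (integer counts), ``normalized`` (per-cell scaled) or ``lognorm``
(scaled then log1p).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "filter_min_count",
    "normalize_and_log",
    "write_results",
    "read_labels",
    "read_matrix_tsv",
]

LAYERS = ("raw", "normalized", "lognorm")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and a layer tag."""

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, g = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g_) for g_ in self.gene_ids]
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != number of rows {n}"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != number of columns {g}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.layer == "raw" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("raw layer must contain integer counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def sparsity(self) -> float:
        """Fraction of zero entries."""
        return float(np.mean(self.values == 0))


def _read_sidecar(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _find_sidecar(mtx_path: Path, names: Sequence[str]) -> Path | None:
    for name in names:
        cand = mtx_path.parent / name
        if cand.exists():
            return cand
    return None


def read_expression(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    barcodes_path: str | os.PathLike | None = None,
    genes_path: str | os.PathLike | None = None,
    genes_as_rows: bool = True,
) -> ExpressionMatrix:
    """Read a count matrix from Matrix Market or delimited text.

    Matrix Market files follow the 10x on-disk convention of genes as rows
    unless ``genes_as_rows=False``; the returned matrix is always oriented
    cells x genes. Sidecar ``barcodes.tsv`` and ``genes.tsv`` /
    ``features.tsv`` files are looked up next to the ``.mtx`` file when not
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "delimited"
    if format not in ("mtx", "delimited"):
        raise ValueError(f"unknown format {format!r}")

    if format == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if genes_as_rows:
            mat = mat.T
        n, g = mat.shape
        if barcodes_path is None:
            barcodes_path = _find_sidecar(path, ["barcodes.tsv", "barcodes.txt"])
        if genes_path is None:
            genes_path = _find_sidecar(
                path, ["genes.tsv", "features.tsv", "genes.txt"]
            )
        cell_ids = _read_sidecar(Path(barcodes_path)) if barcodes_path else []
        gene_ids = _read_sidecar(Path(genes_path)) if genes_path else []
        if cell_ids and len(cell_ids) != n:
            raise ValueError(
                f"{path}: barcode sidecar has {len(cell_ids)} entries but the "
                f"matrix has {n} cells"
            )
        if gene_ids and len(gene_ids) != g:
            raise ValueError(
                f"{path}: gene sidecar has {len(gene_ids)} entries but the "
                f"matrix has {g} genes"
            )
        return ExpressionMatrix(mat, cell_ids, gene_ids, layer="raw")

    # delimited: header row of gene ids, first column of cell ids
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative entries are not valid counts")
    return ExpressionMatrix(
        values, [str(i) for i in df.index], [str(c) for c in df.columns], layer="raw"
    )


def filter_min_count(m: ExpressionMatrix, min_count: int = 1) -> ExpressionMatrix:
    """Drop cells, then genes, whose total count falls below ``min_count``."""
    if m.layer != "raw":
        raise ValueError("filter_min_count expects the raw layer")
    if min_count < 1:
        raise ValueError("min_count must be a positive integer")
    cell_keep = m.values.sum(axis=1) >= min_count
    if not cell_keep.any():
        raise ValueError("filtering removed every cell")
    vals = m.values[cell_keep]
    gene_keep = vals.sum(axis=0) >= min_count
    if not gene_keep.any():
        raise ValueError("filtering removed every gene")
    return ExpressionMatrix(
        vals[:, gene_keep],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
        layer="raw",
    )


def normalize_and_log(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Scale every cell to the same total, then apply log1p."""
    if m.layer != "raw":
        raise ValueError("normalize_and_log expects the raw layer")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-total cell encountered; run filter_min_count first")
    out = np.log1p(m.values / totals[:, None] * scale)
    return ExpressionMatrix(out, list(m.cell_ids), list(m.gene_ids), layer="lognorm")


def write_results(
    labels: Sequence[int],
    embedding: np.ndarray,
    prefix: str | os.PathLike,
    cell_ids: Sequence[str] | None = None,
    precision: int = 8,
) -> tuple[Path, Path]:
    """Write cluster labels and an embedding matrix as TSV files.

    Returns the two written paths ``(<prefix>_labels.tsv,
    <prefix>_embedding.tsv)``.
    """
    labels = np.asarray(labels)
    embedding = np.asarray(embedding, dtype=float)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if embedding.ndim != 2 or embedding.shape[0] != labels.shape[0]:
        raise ValueError(
            f"labels length {labels.shape[0]} does not match embedding rows "
            f"{embedding.shape[0] if embedding.ndim == 2 else embedding.shape}"
        )
    n, d = embedding.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    if len(cell_ids) != n:
        raise ValueError("cell_ids length mismatch")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels_path = prefix.parent / (prefix.name + "_labels.tsv")
    emb_path = prefix.parent / (prefix.name + "_embedding.tsv")
    pd.DataFrame({"cell_id": list(cell_ids), "cluster": labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    emb_df = pd.DataFrame(
        embedding, index=pd.Index(list(cell_ids), name="cell_id")
    )
    emb_df.columns = [f"dim_{j}" for j in range(d)]
    emb_df.to_csv(emb_path, sep="\t", float_format=f"%.{precision}g")
    return labels_path, emb_path


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Read a two-column (cell_id, cluster) TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    if "cluster" in df.columns:
        return df["cluster"].to_numpy()
    return df.iloc[:, -1].to_numpy()


def read_matrix_tsv(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a TSV matrix with a cell_id first column; returns (values, cell_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
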