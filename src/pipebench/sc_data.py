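"""Single-cell expression container and standard-format I/O.

The central type is :class:`SCDataset`: a genes-in-rows, cells-in-columns
count matrix with gene/cell identifiers and optional ground-truth cell
labels, mirroring the Bioconductor ``SingleCellExperiment`` orientation.
Counts are unitless read/UMI counts and must be non-negative integers.

Supported on-disk formats:

* Matrix Market coordinate ``.mtx`` with ``genes.tsv`` / ``barcodes.tsv``
  sidecars (CellRanger-style ``features.tsv`` also accepted);
* dense CSV/TSV with gene ids in the first column and cell ids as header;
* ground-truth labels as a 2-column CSV ``cell_id,label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ValidationError

__all__ = [
    "SCDataset",
    "read_dataset",
    "write_dataset",
    "sample_genes",
    "sample_cells",
    "filter_zero_genes",
]


@dataclass(frozen=True)
class SCDataset:
    """Gene x cell count matrix with identifiers and optional labels.

    Parameters
    ----------
    counts
        Non-negative integer-valued matrix, genes in rows, cells in columns.
        Stored as a dense float64 array; integrality is validated.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell identifiers (barcodes), one per column.
    labels
        Optional ground-truth group label per cell.
    name
        Dataset identifier used in benchmark tables.
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    labels: Optional[tuple[str, ...]] = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene axis mismatch: {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"cell axis mismatch: {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.counts.size and np.min(self.counts) < 0:
            raise ValidationError("negative counts are not allowed")
        if self.counts.size and not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("counts must be integer-valued")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if self.labels is not None and len(self.labels) != n_cells:
            raise ValidationError(
                f"cell axis mismatch: {n_cells} cells but {len(self.labels)} labels"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def with_name(self, name: str) -> "SCDataset":
        return replace(self, name=name)

    def __repr__(self) -> str:  # compact, informative
        lab = "with labels" if self.labels is not None else "no labels"
        return (
            f"SCDataset({self.name!r}: {self.n_genes} genes x "
            f"{self.n_cells} cells, {lab})"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GENE_SIDECARS = ("genes.tsv", "features.tsv")
_CELL_SIDECARS = ("barcodes.tsv",)


def _read_sidecar(directory: Path, candidates: Sequence[str], axis: str) -> list[str]:
    for cand in candidates:
        p = directory / cand
        if p.exists():
            ids = [line.split("\t")[0].strip() for line in p.read_text().splitlines() if line.strip()]
            return ids
    raise FileNotFoundError(
        f"no {axis} sidecar found in {directory} (looked for {', '.join(candidates)})"
    )


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    if path.is_dir():
        directory = path
        mtx_path = directory / "matrix.mtx"
        if not mtx_path.exists():
            mtx_candidates = sorted(directory.glob("*.mtx"))
            if not mtx_candidates:
                raise FileNotFoundError(f"no .mtx file in {directory}")
            mtx_path = mtx_candidates[0]
    else:
        mtx_path = path
        directory = path.parent
    mat = scipy.io.mmread(os.fspath(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    genes = _read_sidecar(directory, _GENE_SIDECARS, "gene")
    cells = _read_sidecar(directory, _CELL_SIDECARS, "cell")
    return mat, genes, cells


def _read_csv(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]


def _read_labels(labels_path: Path, cell_ids: Sequence[str]) -> tuple[str, ...]:
    df = pd.read_csv(labels_path)
    if df.shape[1] < 2:
        raise ValidationError(
            f"labels file {labels_path} must have two columns (cell_id,label)"
        )
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    unknown = set(mapping) - set(cell_ids)
    if unknown:
        raise ValidationError(
            f"labels file references unknown cell ids: {sorted(unknown)[:5]}"
        )
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValidationError(
            f"labels file missing labels for cells: {missing[:5]}"
        )
    return tuple(mapping[c] for c in cell_ids)


def read_dataset(
    path: str | Path,
    format: str = "csv",
    labels_path: str | Path | None = None,
    name: str | None = None,
) -> SCDataset:
    """Read a count dataset from disk.

    ``format="mtx"`` expects a Matrix Market file (or a directory holding
    ``matrix.mtx``) with ``genes.tsv``/``barcodes.tsv`` sidecars; ``"csv"``
    expects a dense table with gene ids in the first column and cell ids as
    header. Labels, when given, are joined to cells by cell id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path does not exist: {path}")
    if format == "mtx":
        counts, genes, cells = _read_mtx(path)
    elif format in {"csv", "tsv"}:
        counts, genes, cells = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")
    labels = None
    if labels_path is not None:
        labels_path = Path(labels_path)
        if not labels_path.exists():
            raise FileNotFoundError(f"labels path does not exist: {labels_path}")
        labels = _read_labels(labels_path, cells)
    if name is None:
        name = path.stem if path.is_file() else path.name
    return SCDataset(counts=counts, gene_ids=tuple(genes), cell_ids=tuple(cells),
                     labels=labels, name=name)


def write_dataset(d: SCDataset, directory: str | Path, format: str = "mtx") -> Path:
    """Write a dataset to ``directory`` in mtx (+sidecars) or csv form.

    Labels, when present, are written as ``labels.csv`` alongside the matrix.
    Returns the directory path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(d.counts.astype(int))
        scipy.io.mmwrite(os.fspath(directory / "matrix.mtx"), sparse)
        (directory / "genes.tsv").write_text("\n".join(d.gene_ids) + "\n")
        (directory / "barcodes.tsv").write_text("\n".join(d.cell_ids) + "\n")
    elif format == "csv":
        df = pd.DataFrame(d.counts.astype(int), index=list(d.gene_ids),
                          columns=list(d.cell_ids))
        df.index.name = "gene"
        df.to_csv(directory / "counts.csv")
    else:
        raise ValueError(f"unknown format {format!r}")
    if d.labels is not None:
        pd.DataFrame({"cell_id": list(d.cell_ids), "label": list(d.labels)}).to_csv(
            directory / "labels.csv", index=False
        )
    return directory


# ---------------------------------------------------------------------------
# Sampling and filtering utilities
# ---------------------------------------------------------------------------


def _check_n(n: int, available: int, axis: str) -> None:
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError(f"n must be an integer, got {n!r}")
    if n < 1 or n > available:
        raise ValueError(
            f"cannot sample {n} {axis} from a dataset with {available} {axis}"
        )


def sample_genes(d: SCDataset, n: int, seed: int) -> SCDataset:
    """Uniform sample without replacement of ``n`` gene rows.

    The retained genes keep their original order (subset, not shuffle); the
    cell axis and labels are unchanged. Deterministic given ``seed``.
    """
    _check_n(n, d.n_genes, "genes")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d.n_genes, size=n, replace=False))
    return replace(
        d,
        counts=d.counts[idx, :],
        gene_ids=tuple(d.gene_ids[i] for i in idx),
    )


def sample_cells(d: SCDataset, n: int, seed: int) -> SCDataset:
    """Uniform sample without replacement of ``n`` cells (columns).

    Labels are subset in lockstep with cells, preserving the cell/label
    pairing. Retained cells keep their original order.
    """
    _check_n(n, d.n_cells, "cells")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d.n_cells, size=n, replace=False))
    labels = None if d.labels is None else tuple(d.labels[i] for i in idx)
    return replace(
        d,
        counts=d.counts[:, idx],
        cell_ids=tuple(d.cell_ids[i] for i in idx),
        labels=labels,
    )


def filter_zero_genes(d: SCDataset) -> SCDataset:
    """Remove genes whose counts are zero across all cells.

    Relative gene order is preserved; an all-zero matrix yields a valid
    0-gene dataset. Idempotent.
    """
    keep = np.flatnonzero(d.counts.sum(axis=1) > 0)
    return replace(
        d,
        counts=d.counts[keep, :],
        gene_ids=tuple(d.gene_ids[i] for i in keep),
    )
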