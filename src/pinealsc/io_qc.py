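"""Count-matrix IO and cell/gene quality control.

QC follows the standard droplet workflow for this tissue: remove cells
expressing fewer than 800 genes, remove cells whose total UMI count exceeds a
per-sample outlier cutoff (suspected doublets), then drop genes detected in
fewer than 3 cells.  Filters are applied in that order because gene-detection
counts depend on which cells survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCReport",
    "read_counts",
    "filter_cells_min_genes",
    "filter_umi_outliers",
    "filter_genes_min_cells",
    "pool_replicates",
]


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x cells."""

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="barcode")
        ng, nc = self.counts.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError(
                f"matrix is {ng}x{nc} but has {len(self.gene_ids)} gene and "
                f"{len(self.cell_ids)} cell identifiers"
            )
        if not self.gene_ids.is_unique:
            dup = self.gene_ids[self.gene_ids.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene identifiers, e.g. {dup}")
        if not self.cell_ids.is_unique:
            dup = self.cell_ids[self.cell_ids.duplicated()][:3].tolist()
            raise ValueError(f"duplicate cell identifiers, e.g. {dup}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected genes (count > 0) per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[:, keep], self.gene_ids,
                           self.cell_ids[keep])

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[keep, :], self.gene_ids[keep],
                           self.cell_ids)


@dataclass
class QCReport:
    """Record of one QC step: what was removed and why."""

    thresholds: dict
    removed_cells: dict[str, list[str]] = field(default_factory=dict)
    removed_genes: list[str] = field(default_factory=list)
    n_cells_in: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "thresholds": self.thresholds,
                "removed_cells": self.removed_cells,
                "removed_genes": self.removed_genes,
                "n_cells_in": self.n_cells_in,
                "n_cells_out": self.n_cells_out,
                "n_genes_in": self.n_genes_in,
                "n_genes_out": self.n_genes_out,
            },
            sort_keys=True,
        )

    def log_lines(self) -> list[str]:
        lines = []
        for reason, cells in self.removed_cells.items():
            lines.append(f"QC: removed {len(cells)} cells ({reason})")
        if self.removed_genes:
            lines.append(f"QC: removed {len(self.removed_genes)} genes")
        return lines


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from an MTX directory or a dense delimited file.

    A directory must contain ``matrix.mtx`` (MatrixMarket coordinate, genes x
    cells) with ``genes.tsv`` and ``barcodes.tsv`` sidecars.  A file is read
    as a dense table, genes in rows (first column) and cells in columns
    (header), comma- or tab-delimited by extension.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"{mtx} not found")
        counts = scipy.io.mmread(mtx)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        return CountMatrix(sp.csr_matrix(counts), pd.Index(genes),
                           pd.Index(barcodes))
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries")
    return CountMatrix(sp.csr_matrix(values), pd.Index(df.index),
                       pd.Index(df.columns))


def filter_cells_min_genes(m: CountMatrix, min_genes: int = 800
                           ) -> tuple[CountMatrix, QCReport]:
    """Remove cells expressing fewer than ``min_genes`` genes (strict <)."""
    detected = m.genes_per_cell()
    keep = detected >= min_genes
    report = QCReport(
        thresholds={"min_genes": min_genes},
        removed_cells={"low-genes": m.cell_ids[~keep].tolist()},
        n_cells_in=m.n_cells, n_cells_out=int(keep.sum()),
        n_genes_in=m.n_genes, n_genes_out=m.n_genes,
    )
    return m.subset_cells(keep), report


def filter_umi_outliers(m: CountMatrix, max_umi: float
                        ) -> tuple[CountMatrix, QCReport]:
    """Remove cells with total UMIs strictly above ``max_umi``.

    The cutoff is sample-specific (no default): outlier totals flag likely
    doublets, and the right bound depends on each library's depth.
    """
    if not max_umi > 0:
        raise ValueError("max_umi must be > 0")
    totals = m.umis_per_cell()
    keep = totals <= max_umi
    report = QCReport(
        thresholds={"max_umi": max_umi},
        removed_cells={"umi-outlier": m.cell_ids[~keep].tolist()},
        n_cells_in=m.n_cells, n_cells_out=int(keep.sum()),
        n_genes_in=m.n_genes, n_genes_out=m.n_genes,
    )
    return m.subset_cells(keep), report


def filter_genes_min_cells(m: CountMatrix, min_cells: int = 3
                           ) -> tuple[CountMatrix, QCReport]:
    """Drop genes detected in fewer than ``min_cells`` cells (strict <)."""
    detected_in = m.cells_per_gene()
    keep = detected_in >= min_cells
    report = QCReport(
        thresholds={"min_cells": min_cells},
        removed_genes=m.gene_ids[~keep].tolist(),
        n_cells_in=m.n_cells, n_cells_out=m.n_cells,
        n_genes_in=m.n_genes, n_genes_out=int(keep.sum()),
    )
    return m.subset_genes(keep), report


def pool_replicates(samples: list[CountMatrix], labels: list[str],
                    *, strict_genes: bool = True) -> CountMatrix:
    """Column-concatenate replicates over their shared gene universe.

    Cell identifiers are prefixed ``label:barcode`` to stay unique.  With
    ``strict_genes`` the intersection of gene sets must be non-empty (an
    empty inner join raises); otherwise an empty matrix is returned.
    """
    if len(samples) != len(labels):
        raise ValueError("one label per sample required")
    if not samples:
        raise ValueError("no samples to pool")
    shared = samples[0].gene_ids
    for s in samples[1:]:
        shared = shared.intersection(s.gene_ids)
    if len(shared) == 0 and strict_genes:
        raise ValueError("samples share no genes")
    shared = pd.Index(sorted(shared), name="gene")

    blocks, cell_ids = [], []
    for s, label in zip(samples, labels):
        idx = s.gene_ids.get_indexer(shared)
        blocks.append(s.counts[idx, :])
        cell_ids.extend(f"{label}:{c}" for c in s.cell_ids)
    ids = pd.Index(cell_ids, name="barcode")
    if not ids.is_unique:
        raise ValueError("colliding cell identifiers after prefixing")
    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((0, 0))
    return CountMatrix(counts, shared, ids)
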