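"""Normalization, log transform, highly variable gene selection and scaling.

Counts are normalized to 10,000 molecules per cell, natural-log transformed
(ln(x+1)), and highly variable genes (HVGs) are selected by dispersion
relative to expression-matched genes: genes are binned by mean expression and
the log variance-to-mean ratio is z-scored within each bin.  Default cutoffs
(x_low=0.0125, x_high=3, y=0.3) typically select on the order of a thousand
genes.  Selected genes are z-scaled per gene before PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "HVGSelection",
    "HVGCutoffs",
    "normalize_per_cell",
    "log_transform",
    "select_hvg",
    "scale_genes",
]


@dataclass
class NormalizedMatrix:
    """Dense genes x cells expression matrix with a processing-scheme tag.

    ``scheme`` is one of ``per10k`` (counts per 10,000), ``ln`` (natural log
    of per-10k plus one) or ``scaled`` (per-gene z-scores).
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    scheme: str
    parent: CountMatrix | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("per10k", "ln", "scaled"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError("identifier lists do not match matrix dims")

    def gene_row(self, gene: str) -> np.ndarray:
        i = self.gene_ids.get_loc(gene)
        return self.values[i]

    def subset_genes(self, genes) -> "NormalizedMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = pd.Index(genes)[idx < 0][:3].tolist()
            raise KeyError(f"genes not present, e.g. {missing}")
        return NormalizedMatrix(self.values[idx], self.gene_ids[idx],
                                self.cell_ids, self.scheme, self.parent)

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values[:, mask_or_idx], self.gene_ids,
                                self.cell_ids[mask_or_idx], self.scheme,
                                self.parent)


@dataclass(frozen=True)
class HVGCutoffs:
    x_low: float = 0.0125
    x_high: float = 3.0
    y: float = 0.3


@dataclass
class HVGSelection:
    """Per-gene HVG statistics plus the selected gene list."""

    table: pd.DataFrame  # columns: mean_stat, dispersion, z, selected
    cutoffs: HVGCutoffs
    n_bins: int

    @property
    def genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def normalize_per_cell(m: CountMatrix, scale_total: float = 10_000
                       ) -> NormalizedMatrix:
    """Scale each cell's counts to sum to ``scale_total`` (default 10,000)."""
    totals = m.umis_per_cell().astype(float)
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][:3].tolist()
        raise ValueError(f"zero-total cells, e.g. {bad}; run QC first")
    dense = np.asarray(m.counts.todense(), dtype=float)
    values = dense * (scale_total / totals)[None, :]
    return NormalizedMatrix(values, m.gene_ids.copy(), m.cell_ids.copy(),
                            "per10k", parent=m)


def log_transform(m: NormalizedMatrix) -> NormalizedMatrix:
    """Natural-log transform, x -> ln(x + 1).  Requires per-10k input."""
    if m.scheme != "per10k":
        raise ValueError(f"log_transform expects scheme 'per10k', got {m.scheme!r}")
    return NormalizedMatrix(np.log1p(m.values), m.gene_ids, m.cell_ids,
                            "ln", parent=m.parent)


def select_hvg(m: NormalizedMatrix, cutoffs: HVGCutoffs | None = None,
               n_bins: int = 20) -> HVGSelection:
    """Dispersion-based HVG selection on the log-transformed matrix.

    Per gene: mean_stat = ln(mean(exp(x) - 1) + 1) over cells (the log of the
    mean un-logged normalized count), dispersion = ln(var/mean) of the
    un-logged normalized counts.  Genes are binned into ``n_bins`` equal-width
    bins of mean_stat and the dispersion is z-scored within each bin (bins
    with a single gene or zero spread get z = 0).  A gene is selected iff
    x_low < mean_stat < x_high and z > y.
    """
    if m.scheme != "ln":
        raise ValueError("select_hvg expects the log-transformed matrix")
    cutoffs = cutoffs or HVGCutoffs()
    unlogged = np.expm1(m.values)
    mean = unlogged.mean(axis=1)
    var = unlogged.var(axis=1, ddof=1) if m.values.shape[1] > 1 else np.zeros_like(mean)
    mean_stat = np.log1p(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.log(var / mean)
    dispersion[~np.isfinite(dispersion)] = np.nan

    # Equal-width bins over the observed mean_stat range; edge ties go low.
    lo, hi = float(mean_stat.min()), float(mean_stat.max())
    if hi > lo:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.searchsorted(edges, mean_stat, side="left") - 1
        bins = np.clip(bins, 0, n_bins - 1)
    else:
        bins = np.zeros(len(mean_stat), dtype=int)

    z = np.zeros(len(mean_stat))
    for b in range(n_bins):
        in_bin = (bins == b) & np.isfinite(dispersion)
        if in_bin.sum() < 2:
            continue
        d = dispersion[in_bin]
        sd = d.std(ddof=1)
        if sd > 0:
            z[in_bin] = (d - d.mean()) / sd

    selected = (mean_stat > cutoffs.x_low) & (mean_stat < cutoffs.x_high) \
        & (z > cutoffs.y)
    table = pd.DataFrame(
        {"mean_stat": mean_stat, "dispersion": dispersion, "z": z,
         "selected": selected},
        index=m.gene_ids,
    )
    return HVGSelection(table=table, cutoffs=cutoffs, n_bins=n_bins)


def scale_genes(m: NormalizedMatrix, genes, clip: float | None = 10.0
                ) -> NormalizedMatrix:
    """Z-scale the given genes across cells (zero mean, unit sd per gene).

    Zero-variance genes become all-zero rows.  Scaled values are clipped at
    +/- ``clip`` (pass None to disable) to bound outlier influence on PCA.
    """
    if m.scheme != "ln":
        raise ValueError("scale_genes expects the log-transformed matrix")
    sub = m.subset_genes(genes)
    mu = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, ddof=1, keepdims=True) if sub.values.shape[1] > 1 \
        else np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (sub.values - mu) / sd
    scaled[~np.isfinite(scaled)] = 0.0
    if clip is not None:
        scaled = np.clip(scaled, -clip, clip)
    return NormalizedMatrix(scaled, sub.gene_ids, sub.cell_ids, "scaled",
                            parent=m.parent)
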