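"""Quality control and normalization of a count matrix.

Cells expressing fewer than 800 genes are removed, cells with outlier UMI
totals (a per-sample cutoff; here 30,000) are removed as suspected doublets,
and genes detected in fewer than 3 cells are dropped.  Counts are then
normalized to 10,000 molecules per cell and natural-log transformed.
"""

import numpy as np

from pinealsc import (
    default_pineal_config,
    filter_cells_min_genes,
    filter_genes_min_cells,
    filter_umi_outliers,
    log_transform,
    normalize_per_cell,
    select_hvg,
    simulate,
)

matrix, truth = simulate(default_pineal_config(n_cells=3000, seed=2))
print(f"input: {matrix.n_genes} genes x {matrix.n_cells} cells")

matrix, r1 = filter_cells_min_genes(matrix, min_genes=800)
matrix, r2 = filter_umi_outliers(matrix, max_umi=30_000)
matrix, r3 = filter_genes_min_cells(matrix, min_cells=3)
for r in (r1, r2, r3):
    for line in r.log_lines():
        print(line)
print(f"after QC: {matrix.n_genes} genes x {matrix.n_cells} cells")

norm = normalize_per_cell(matrix)
print(f"column sums after per-cell normalization: "
      f"{np.unique(np.round(norm.values.sum(axis=0), 6))}")

hvg = select_hvg(log_transform(norm))
print(f"highly variable genes selected: {len(hvg.genes)} "
      f"(dispersion z > 0.3 within expression bins)")
print("a few of them:", sorted(hvg.genes)[:8])
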