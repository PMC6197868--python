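"""Generate a synthetic pineal-gland dataset and inspect its ground truth.

The default configuration emulates the gland's nine cell types at their
observed proportions (90% pinealocytes at a 5:95 alpha:beta split, 7%
astrocytes, 1% microglia, ~2% VLMCs, 0.1% endothelial cells), with ambient
contamination from lysed pinealocytes and ~1.5% doublets.
"""

from pinealsc import default_pineal_config, simulate, write_dataset

config = default_pineal_config(n_cells=5000, seed=1)
matrix, truth = simulate(config)

print(f"matrix: {matrix.n_genes} genes x {matrix.n_cells} cells, "
      f"{matrix.counts.nnz} non-zero entries")
print(f"median UMIs per cell: {int(__import__('numpy').median(matrix.umis_per_cell()))}")
print("\nplanted cell-type composition (families):")
print(truth.cells["family"].value_counts().to_string())
print("\nfirst planted condition effects:")
print(truth.gene_effects.head(5).to_string(index=False))

manifest = write_dataset(matrix, truth, "scratch/example_dataset",
                         config=config)
print(f"\nwrote {len(manifest['files'])} files to scratch/example_dataset "
      "(MatrixMarket counts + TSV sidecars + ground truth)")
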