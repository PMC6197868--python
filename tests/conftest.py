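"""Shared fixtures: small synthetic datasets and (session-scoped) full
pipeline runs on the default pineal configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pinealsc import (
    CountMatrix,
    default_pineal_config,
    filter_cells_min_genes,
    filter_genes_min_cells,
    filter_umi_outliers,
    simulate,
)
from pinealsc.pipeline import RunConfig, analyze_sample, _qc_sample
from pinealsc.simulate import CellTypeSpec, SimConfig


def toy_matrix(counts, genes=None, cells=None) -> CountMatrix:
    counts = np.asarray(counts)
    ng, nc = counts.shape
    genes = genes or [f"g{i}" for i in range(ng)]
    cells = cells or [f"c{j}" for j in range(nc)]
    return CountMatrix(sp.csr_matrix(counts), pd.Index(genes), pd.Index(cells))


def single_type_config(n_cells=400, n_genes=50, seed=0, **kw) -> SimConfig:
    """One pinealocyte population, no effects, no ambient, no doublets."""
    rng = np.random.default_rng(seed)
    baseline = rng.dirichlet(np.full(n_genes, 5.0))
    ctype = CellTypeSpec(name="beta-pinealocyte", proportion=1.0,
                         baseline=baseline)
    defaults = dict(ambient_fraction=0.0, doublet_rate=0.0,
                    depth_log_mean=np.log(3000.0), depth_log_sd=0.2)
    defaults.update(kw)
    return SimConfig(n_cells=n_cells, gene_ids=[f"g{i}" for i in range(n_genes)],
                     cell_types=[ctype], seed=seed, **defaults)


@pytest.fixture(scope="session")
def default_sim():
    """Default 5,000-cell pineal dataset with ground truth (seed 1)."""
    cfg = default_pineal_config(5000, 1)
    matrix, truth = simulate(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_sim():
    """2,000-cell default dataset for cheaper integration tests."""
    cfg = default_pineal_config(2000, 7)
    matrix, truth = simulate(cfg)
    return cfg, matrix, truth


def run_default_pipeline(seed: int, n_cells: int = 5000):
    """QC + per-condition clustering/annotation on one default simulation.

    Returns (truth, {condition: SampleResult}).
    """
    cfg = default_pineal_config(n_cells, seed)
    matrix, truth = simulate(cfg)
    rc = RunConfig(out_dir="unused", seed=seed, simulate_n_cells=n_cells,
                   max_umi=30_000)
    results = {}
    condition = truth.cells["condition"]
    for cond in ("day", "night"):
        keep = condition.reindex(matrix.cell_ids).eq(cond).to_numpy()
        sub, reports = _qc_sample(matrix.subset_cells(keep), cond, rc)
        results[cond] = analyze_sample(sub, cond, rc, qc_reports=reports)
    return truth, results


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full per-condition pipeline on the default generator, seeds 1-3."""
    return {seed: run_default_pipeline(seed) for seed in (1, 2, 3)}
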