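"""End-to-end orchestration: simulate/read -> QC -> per-condition clustering
and annotation -> cross-condition differential expression -> summaries.

Each condition sample (day, night; or vehicle, drug) is clustered on its own
— condition effects otherwise dominate the embedding and split every cell
type by condition — with a condition-specific number of principal components
(defaults 13 day / 10 night / 8 vehicle / 7 isoproterenol).  Cell types are
then matched across conditions by their panel annotation, and the composite
DE rule is applied per cell type between conditions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_qc, preprocess
from .clustering import (
    ClusterModel,
    ConsolidationRule,
    build_snn,
    cluster_proportions,
    cluster_tree,
    consolidate,
    exclude_doublets,
    find_communities,
    run_pca,
    tree_to_newick,
)
from .diffexp import (
    DECriteria,
    GeneGroup,
    ambient_exclusion,
    de_overlap,
    de_test,
    group_comparison,
)
from .markers import DEFAULT_PANEL, ReferencePanel, annotate_clusters, find_markers
from .preprocess import HVGCutoffs
from .simulate import default_pineal_config, family_of, simulate, write_dataset

logger = logging.getLogger("pinealsc")

__all__ = ["RunConfig", "SampleResult", "run_pipeline", "analyze_sample", "report"]

DEFAULT_N_PCS = {"day": 13, "night": 10, "vehicle": 8, "isoproterenol": 7}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``simulate_n_cells`` (synthetic data from the default pineal
    generator) or ``input_path`` + ``sample_sheet`` (MTX/dense counts with a
    per-cell condition column) must be provided.  ``max_umi`` is the
    per-sample UMI outlier cutoff and has no default: it is sample-specific
    and must be stated explicitly.
    """

    out_dir: str | Path
    seed: int = 0
    # input: synthetic ...
    simulate_n_cells: int | None = None
    simulate_overrides: dict = field(default_factory=dict)
    # ... or files
    input_path: str | Path | None = None
    sample_sheet: str | Path | None = None
    # QC
    min_genes: int = 800
    max_umi: float | dict | None = None
    min_cells_per_gene: int = 3
    # preprocessing / clustering
    hvg_cutoffs: HVGCutoffs = field(default_factory=HVGCutoffs)
    n_pcs: dict = field(default_factory=lambda: dict(DEFAULT_N_PCS))
    knn_k: int = 30
    prune: float = 1 / 15
    resolution: float = 0.8
    # annotation / DE
    panel: ReferencePanel = field(default_factory=lambda: DEFAULT_PANEL)
    criteria: DECriteria = field(default_factory=DECriteria)
    ambient_genes: tuple[str, ...] = ("Aanat",)
    manual_assignments: dict = field(default_factory=dict)
    gene_groups: list[GeneGroup] = field(default_factory=list)

    def validate(self) -> None:
        has_sim = self.simulate_n_cells is not None
        has_files = self.input_path is not None
        if has_sim == has_files:
            raise ValueError("provide exactly one of simulate_n_cells or input_path")
        if self.max_umi is None:
            raise ValueError(
                "max_umi (per-sample UMI outlier cutoff) is required; "
                "it is sample-specific and has no default"
            )
        if has_files and self.sample_sheet is None:
            raise ValueError("input_path requires a sample_sheet with conditions")

    def umi_cutoff(self, sample: str) -> float:
        if isinstance(self.max_umi, dict):
            if sample not in self.max_umi:
                raise ValueError(f"no max_umi for sample {sample!r}")
            return float(self.max_umi[sample])
        return float(self.max_umi)


@dataclass
class SampleResult:
    """Per-condition clustering artifacts."""

    condition: str
    matrix: io_qc.CountMatrix
    norm: preprocess.NormalizedMatrix
    hvg: preprocess.HVGSelection
    model: ClusterModel
    annotation: pd.DataFrame
    marker_tables: dict
    qc_reports: list

    @property
    def cell_types(self) -> pd.Series:
        """Per-cell annotated type (NaN for excluded cells)."""
        return self.model.labels.map(self.annotation["type"])


def analyze_sample(matrix: io_qc.CountMatrix, condition: str, cfg: RunConfig,
                   qc_reports: list | None = None) -> SampleResult:
    """Cluster and annotate one QC'ed condition sample."""
    norm = preprocess.normalize_per_cell(matrix)
    ln = preprocess.log_transform(norm)
    hvg = preprocess.select_hvg(ln, cfg.hvg_cutoffs)
    scaled = preprocess.scale_genes(ln, hvg.genes)
    k = int(cfg.n_pcs.get(condition, max(cfg.n_pcs.values(), default=10)))
    k = min(k, min(scaled.values.shape) - 1)
    pca = run_pca(scaled, k=k)
    snn = build_snn(pca, knn_k=min(cfg.knn_k, matrix.n_cells - 1),
                    prune=cfg.prune)
    raw = find_communities(snn, resolution=cfg.resolution, seed=cfg.seed)
    model = consolidate(norm, raw,
                        ConsolidationRule(criteria=cfg.criteria, seed=cfg.seed))
    marker_tables = {
        c: find_markers(norm, model.labels, c, mode="roc")
        for c in model.final_clusters()
    }
    model = exclude_doublets(norm, model)
    annotation = annotate_clusters(norm, model.labels, cfg.panel)
    manual = cfg.manual_assignments.get(condition)
    if manual:
        # Barcode-level identity overrides (e.g. endothelial cells embedded
        # within another cluster): assign the listed barcodes to a new
        # cluster carrying the stated type.
        labels = model.labels.copy()
        next_id = (max([c for c in model.final_clusters()], default=-1) or 0)
        for type_name, barcodes in manual.items():
            next_id = next_id + 1
            labels.loc[labels.index.isin(barcodes)] = next_id
            annotation.loc[next_id] = {
                "family": family_of(type_name), "type": type_name,
                "score": float("nan"), "margin": float("nan"),
                "n_cells": int(labels.index.isin(barcodes).sum()),
            }
        model.labels = labels
    if len(model.final_clusters()) >= 2:
        model = cluster_tree(norm, model, hvg)
    return SampleResult(condition=condition, matrix=matrix, norm=norm,
                        hvg=hvg, model=model, annotation=annotation,
                        marker_tables=marker_tables,
                        qc_reports=qc_reports or [])


def _qc_sample(m: io_qc.CountMatrix, sample: str, cfg: RunConfig
               ) -> tuple[io_qc.CountMatrix, list]:
    reports = []
    m, r1 = io_qc.filter_cells_min_genes(m, cfg.min_genes)
    reports.append(r1)
    m, r2 = io_qc.filter_umi_outliers(m, cfg.umi_cutoff(sample))
    reports.append(r2)
    m, r3 = io_qc.filter_genes_min_cells(m, cfg.min_cells_per_gene)
    reports.append(r3)
    for r in reports:
        for line in r.log_lines():
            logger.info("%s: %s", sample, line)
    return m, reports


def _load_input(cfg: RunConfig) -> tuple[io_qc.CountMatrix, pd.Series, object]:
    """Returns (counts, per-cell condition Series, truth-or-None)."""
    if cfg.simulate_n_cells is not None:
        sim_cfg = default_pineal_config(cfg.simulate_n_cells, cfg.seed,
                                        **cfg.simulate_overrides)
        matrix, truth = simulate(sim_cfg)
        condition = truth.cells["condition"].copy()
        return matrix, condition, (sim_cfg, truth)
    matrix = io_qc.read_counts(cfg.input_path)
    sheet = pd.read_csv(cfg.sample_sheet, sep=None, engine="python",
                        index_col=0)
    if "condition" not in sheet.columns:
        raise ValueError("sample_sheet needs a 'condition' column")
    condition = sheet["condition"].reindex(matrix.cell_ids)
    if condition.isna().any():
        missing = matrix.cell_ids[condition.isna()][:3].tolist()
        raise ValueError(f"cells missing from sample sheet, e.g. {missing}")
    if "replicate" in sheet.columns:
        reps = sheet["replicate"].reindex(matrix.cell_ids)
        logger.info("replicates pooled per condition: %s",
                    reps.groupby(condition).nunique().to_dict())
    return matrix, condition, None


def _config_jsonable(cfg: RunConfig) -> dict:
    """Serialize a RunConfig (full provenance record of one run)."""
    from dataclasses import asdict

    out = {}
    for name in RunConfig.__dataclass_fields__:
        value = getattr(cfg, name)
        if name == "panel":
            out[name] = value.markers
        elif name == "criteria" or name == "hvg_cutoffs":
            out[name] = asdict(value)
        elif name == "gene_groups":
            out[name] = {g.name: list(g.genes) for g in value}
        else:
            out[name] = str(value) if isinstance(value, Path) else value
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write tables to ``out_dir``; return the
    manifest.  Re-running with the same config is deterministic."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {"seed": config.seed, "files": {}, "stages": []}

    def emit(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", **kw)
        manifest["files"][name] = name

    with open(out / "run_config.json", "w") as fh:
        json.dump(_config_jsonable(config), fh, sort_keys=True, indent=1)
    manifest["files"]["run_config.json"] = "run_config.json"

    matrix, condition, sim = _load_input(config)
    if sim is not None:
        write_dataset(matrix, sim[1], out / "simulated", config=sim[0])
        manifest["files"]["simulated"] = "simulated/"
    manifest["stages"].append({"stage": "input", "n_cells": matrix.n_cells,
                               "n_genes": matrix.n_genes})

    conditions = sorted(condition.dropna().unique())
    results: dict[str, SampleResult] = {}
    for cond in conditions:
        sub = matrix.subset_cells(condition.reindex(matrix.cell_ids)
                                  .eq(cond).to_numpy())
        sub, reports = _qc_sample(sub, cond, config)
        res = analyze_sample(sub, cond, config, qc_reports=reports)
        results[cond] = res
        emit(f"clusters_{cond}.tsv",
             pd.DataFrame({"raw_cluster": res.model.raw_labels,
                           "final_cluster": res.model.labels,
                           "type": res.cell_types}))
        emit(f"annotation_{cond}.tsv", res.annotation)
        props = cluster_proportions(res.model, res.annotation)
        emit(f"proportions_{cond}.tsv", props, index=False)
        if res.model.dendrogram is not None:
            names = res.annotation["type"].to_dict()
            (out / f"dendrogram_{cond}.nwk").write_text(
                tree_to_newick(res.model, names) + "\n")
            manifest["files"][f"dendrogram_{cond}.nwk"] = f"dendrogram_{cond}.nwk"
        with open(out / f"qc_{cond}.json", "w") as fh:
            fh.write("[" + ",".join(r.to_json() for r in reports) + "]")
        manifest["files"][f"qc_{cond}.json"] = f"qc_{cond}.json"
        manifest["stages"].append({
            "stage": f"cluster:{cond}", "n_cells": sub.n_cells,
            "n_hvg": len(res.hvg.genes),
            "n_clusters": len(res.model.final_clusters()),
            "n_doublets_excluded": int(len(res.model.excluded)),
        })

    # Cross-condition DE on the pooled QC'ed samples.
    summary: dict = {"proportions": {}, "de_counts": {}, "group_ratios": {}}
    for cond, res in results.items():
        props = cluster_proportions(res.model, res.annotation)
        summary["proportions"][cond] = props.set_index("type")[
            ["n_cells", "pct_of_total", "pct_of_family"]
        ].round(3).to_dict("index")

    de_sets: dict[str, set] = {}
    if len(conditions) == 2:
        pooled = io_qc.pool_replicates(
            [results[c].matrix for c in conditions], list(conditions))
        pooled_norm = preprocess.normalize_per_cell(pooled)
        ann_cells = pd.concat([
            results[c].cell_types.rename(index=lambda b, c=c: f"{c}:{b}")
            for c in conditions
        ]).reindex(pooled.cell_ids)
        cond_cells = pd.Series(
            [c.split(":", 1)[0] for c in pooled.cell_ids],
            index=pooled.cell_ids)
        exclusions = ambient_exclusion(
            sorted(ann_cells.dropna().unique()), default=config.ambient_genes)
        de_tables = []
        for ctype in sorted(ann_cells.dropna().unique()):
            n_by_cond = cond_cells[ann_cells == ctype].value_counts()
            if len(n_by_cond) < 2 or n_by_cond.min() < 3:
                logger.warning("skipping DE for %s: too few cells", ctype)
                continue
            table = de_test(pooled_norm, ann_cells, ctype, cond_cells,
                            config.criteria, exclusions[ctype],
                            condition_order=(conditions[0], conditions[1]))
            de_tables.append(table)
            de = table[table["de"]]
            up_a = set(de.index[de["direction"] == f"{conditions[1]}-up"])
            up_b = set(de.index[de["direction"] == f"{conditions[0]}-up"])
            summary["de_counts"][ctype] = {
                f"{conditions[1]}-up": len(up_a),
                f"{conditions[0]}-up": len(up_b),
            }
            de_sets[f"{ctype}:{conditions[1]}-up"] = up_a
            de_sets[f"{ctype}:{conditions[0]}-up"] = up_b
        if de_tables:
            emit("de_results.tsv", pd.concat(de_tables))
        overlap_sets = {k: v for k, v in de_sets.items() if v}
        if len(overlap_sets) >= 2:
            overlaps = de_overlap(overlap_sets)
            emit("de_overlaps.tsv", overlaps, index=False)
            manifest["stages"].append({"stage": "overlap",
                                       "n_sets": len(overlap_sets)})

        if config.gene_groups:
            # Pool every non-alpha pinealocyte cluster into one beta-side
            # group: algorithmic sub-splits of the large beta population
            # must not shrink the comparison.
            def pineal_side(t):
                if family_of(t) != "pinealocyte":
                    return t
                return t if t == "alpha-pinealocyte" else "beta-pinealocyte-pool"

            ann_pineal = ann_cells.map(pineal_side, na_action="ignore")
            sides = set(ann_pineal.dropna())
            if {"alpha-pinealocyte", "beta-pinealocyte-pool"} <= sides:
                for group in config.gene_groups:
                    r = group_comparison(pooled_norm, ann_pineal, group,
                                         "alpha-pinealocyte",
                                         "beta-pinealocyte-pool")
                    summary["group_ratios"][group.name] = {
                        "type_a": "alpha-pinealocyte",
                        "type_b": "beta-pinealocyte-pool",
                        "ratio": r["ratio"], "fold": r["fold"], "p": r["p"],
                    }

    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=str)
    manifest["files"]["summary.json"] = "summary.json"
    manifest["summary"] = summary
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    return manifest


def report(manifest: dict) -> str:
    """Render a run manifest as a human-readable text report."""
    if "summary" not in manifest:
        raise ValueError("incomplete manifest: no summary")
    s = manifest["summary"]
    lines = ["pinealsc run report", "=" * 40]
    for cond, props in s.get("proportions", {}).items():
        lines.append(f"\nCell-type proportions ({cond}):")
        lines.append(f"  {'type':<22}{'n':>7}{'% total':>9}{'% family':>10}")
        for t, row in sorted(props.items(),
                             key=lambda kv: -kv[1]["n_cells"]):
            lines.append(
                f"  {t:<22}{row['n_cells']:>7}"
                f"{row['pct_of_total']:>9.1f}{row['pct_of_family']:>10.1f}"
            )
    if s.get("de_counts"):
        lines.append("\nDE gene counts per cell type:")
        for t, counts in sorted(s["de_counts"].items()):
            parts = ", ".join(f"{k}: {v}" for k, v in sorted(counts.items()))
            lines.append(f"  {t:<22}{parts}")
    else:
        lines.append("\nDE gene counts per cell type: none computed")
    if s.get("group_ratios"):
        lines.append("\nGene-group expression ratios (alpha vs beta pinealocyte):")
        for g, row in sorted(s["group_ratios"].items()):
            lines.append(f"  {g:<12}fold {row['fold']:.2f}  p {row['p']:.3g}")
    lines.append(f"\nruntime: {s.get('runtime_s', '?')} s")
    return "\n".join(lines)
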