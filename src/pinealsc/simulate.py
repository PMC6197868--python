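"""Synthetic pineal-gland scRNA-seq count generator.

Generates UMI count matrices with the statistical structure of a dissociated
rat pineal gland: nine cell types at fixed proportions (two pinealocyte, three
astrocyte and two microglia subtypes, VLMCs and endothelial cells), exclusive
marker-gene programs, planted alpha-vs-beta pinealocyte expression modules
(Asmt, OxPhos, ribosomal, G-protein gamma-subunits), day/night condition
effects, ambient contamination by the pooled pinealocyte profile, lognormal
library-size variation and rare doublets.  Every cell and gene carries ground
truth, so downstream stages (clustering, annotation, differential expression)
are testable by parameter recovery.

The generative model, per singlet cell c of type t in condition v:

    lambda_{g,c} = L_c * [ (1 - a) * p_{t,g} * e_{v,g}  +  a * q_g ]

where L_c is a lognormal library size, p_{t,g} the type's normalized
program-adjusted expression profile, e_{v,g} the condition fold (1 outside the
effect set), a the ambient fraction and q_g the proportion-weighted mean
pinealocyte profile (ambient mRNA from lysed pinealocytes, by far the most
abundant cell).  Counts are Poisson given lambda.  Doublets average the rate
vectors of two independently drawn singlets at weight 0.5 each.
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
    "GeneProgram",
    "CellTypeSpec",
    "ConditionEffect",
    "SimConfig",
    "GroundTruth",
    "default_pineal_config",
    "simulate",
    "write_dataset",
    "family_of",
]

# Canonical cell-type proportions: 90% pinealocytes (5:95 alpha:beta),
# 7% astrocytes (85/7/8), 1% microglia (64/36), 0.1% endothelial, and VLMCs
# as the ~2% vascular remainder (so the shares sum to exactly 1).
PINEAL_PROPORTIONS: dict[str, float] = {
    "alpha-pinealocyte": 0.90 * 0.05,
    "beta-pinealocyte": 0.90 * 0.95,
    "alpha-astrocyte": 0.07 * 0.85,
    "beta-astrocyte": 0.07 * 0.07,
    "gamma-astrocyte": 0.07 * 0.08,
    "alpha-microglia": 0.01 * 0.64,
    "beta-microglia": 0.01 * 0.36,
    "VLMC": 0.019,
    "endothelial": 0.001,
}

# Planted alpha-pinealocyte modules, multiplier relative to beta-pinealocytes.
ASMT_FOLD = 3.4
OXPHOS_FOLD = 2.3
RIBO_FOLD = 1.0 / 8.2
GNG_FOLD = 1.0 / 5.4

OXPHOS_GENES = [
    "Ndufa1", "Ndufa2", "Ndufb4", "Cox4i1", "Cox6a1", "Cox7b", "Uqcrb", "Atp5e",
]
RIBO_GENES = [
    "Rpl3", "Rpl4", "Rpl5", "Rpl6", "Rpl7", "Rpl8", "Rpl13", "Rpl15",
    "Rpl18", "Rpl21", "Rps2", "Rps3", "Rps4x", "Rps5", "Rps6", "Rps7",
    "Rps8", "Rps9", "Rps10", "Rps15a",
]
GNG_GENES = ["Gngt1", "Gngt2", "Gng10", "Gng13"]


def family_of(cell_type: str) -> str:
    """Major-type family of a subtype label (``alpha-astrocyte -> astrocyte``)."""
    for fam in ("pinealocyte", "astrocyte", "microglia"):
        if cell_type.endswith(fam):
            return fam
    return cell_type


@dataclass(frozen=True)
class GeneProgram:
    """A named set of genes enriched (or depleted) in particular cell types.

    ``enrichment`` multiplies the baseline weight of every gene in the program
    within the target types; values < 1 plant depletion modules.
    """

    name: str
    genes: tuple[str, ...]
    enrichment: float

    def __post_init__(self) -> None:
        if self.enrichment <= 0:
            raise ValueError(f"program {self.name}: enrichment must be > 0")
        if not self.genes:
            raise ValueError(f"program {self.name}: gene list is empty")


@dataclass
class CellTypeSpec:
    """One cell type: its share of cells and its expression profile."""

    name: str
    proportion: float
    baseline: np.ndarray  # per-gene relative expression, sums to 1
    programs: list[GeneProgram] = field(default_factory=list)

    def validate(self) -> None:
        if not (0 <= self.proportion <= 1):
            raise ValueError(f"{self.name}: proportion outside [0, 1]")
        if np.any(self.baseline < 0):
            raise ValueError(f"{self.name}: negative baseline entries")
        if abs(float(self.baseline.sum()) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: baseline does not sum to 1")


@dataclass(frozen=True)
class ConditionEffect:
    """A gene whose expression is multiplied by ``fold`` in the night (or
    drug) condition within the listed cell types.  fold != 1 marks true DE."""

    gene: str
    target_types: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"effect on {self.gene}: fold must be > 0")


@dataclass
class SimConfig:
    """Full generative parameterization of one synthetic dataset."""

    n_cells: int
    gene_ids: list[str]
    cell_types: list[CellTypeSpec]
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    conditions: tuple[str, str] = ("day", "night")
    ambient_fraction: float = 0.02
    depth_log_mean: float = float(np.log(8000.0))
    depth_log_sd: float = 0.35
    doublet_rate: float = 0.015
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if not (0 <= self.ambient_fraction < 1):
            raise ValueError("ambient_fraction must be in [0, 1)")
        if not (0 <= self.doublet_rate <= 0.05):
            raise ValueError("doublet_rate must be in [0, 0.05]")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be >= 0")
        if len(set(self.gene_ids)) != self.n_genes:
            raise ValueError("duplicate gene identifiers")
        total = sum(t.proportion for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        for t in self.cell_types:
            if t.baseline.shape != (self.n_genes,):
                raise ValueError(f"{t.name}: baseline length != n_genes")
            t.validate()

    def type_profiles(self) -> pd.DataFrame:
        """Normalized per-type expression profiles, genes x types."""
        return pd.DataFrame(
            {t.name: t.baseline for t in self.cell_types}, index=self.gene_ids
        )

    def pinealocyte_profile(self) -> np.ndarray:
        """Proportion-weighted mean pinealocyte profile (the ambient pool)."""
        w = np.zeros(self.n_genes)
        total = 0.0
        for t in self.cell_types:
            if family_of(t.name) == "pinealocyte":
                w += t.proportion * t.baseline
                total += t.proportion
        if total == 0:
            raise ValueError("no pinealocyte type in config")
        return w / total

    def to_jsonable(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "gene_ids": list(self.gene_ids),
            "conditions": list(self.conditions),
            "ambient_fraction": self.ambient_fraction,
            "depth_log_mean": self.depth_log_mean,
            "depth_log_sd": self.depth_log_sd,
            "doublet_rate": self.doublet_rate,
            "seed": self.seed,
            "cell_types": [
                {
                    "name": t.name,
                    "proportion": t.proportion,
                    "baseline": [round(float(x), 12) for x in t.baseline],
                    "programs": [
                        {"name": p.name, "genes": list(p.genes), "enrichment": p.enrichment}
                        for p in t.programs
                    ],
                }
                for t in self.cell_types
            ],
            "condition_effects": [
                {"gene": e.gene, "target_types": list(e.target_types), "fold": e.fold}
                for e in self.condition_effects
            ],
        }


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset.

    ``cells`` is indexed by barcode with columns cell_type, family, condition,
    is_doublet, type_a, type_b, library_size.  ``gene_effects`` has one row
    per (gene, cell type) condition effect with its true fold.  ``programs``
    records planted program membership with the enrichment used.
    """

    cells: pd.DataFrame
    gene_effects: pd.DataFrame
    programs: pd.DataFrame


# ---------------------------------------------------------------------------
# Default configuration: the nine-type pineal gland
# ---------------------------------------------------------------------------

# Exclusive family / subtype marker genes with their target expression share
# (fraction of the cell's transcriptome).  Chosen to mimic strongly expressed,
# type-restricted markers; outside the target type each marker keeps a small
# residual weight so enrichment is a finite multiplier.
_FAMILY_MARKERS: dict[str, dict[str, float]] = {
    "pinealocyte": {
        "Tph1": 0.005, "Sag": 0.006, "Aanat": 0.003, "Crx": 0.002,
        "Rom1": 0.002, "Cngb1": 0.0015, "Cnga1": 0.0015, "Pde6c": 0.0015,
        "Slc6a6": 0.002, "Drd4": 0.001, "Chrna3": 0.001, "Chrnb4": 0.001,
        "Gngt1": 0.002, "Gngt2": 0.002, "Gng10": 0.0015, "Gng13": 0.0015,
        "Asmt": 0.004,
    },
    "astrocyte": {
        "Aldh1a1": 0.004, "S100b": 0.004, "Tnfrsf21": 0.003,
        "Penk": 0.003, "Apoe": 0.004, "Esm1": 0.002,
    },
    "microglia": {
        "Aif1": 0.005, "Lyz2": 0.004, "Ptprc": 0.003, "Cx3cr1": 0.003,
    },
    "VLMC": {
        "Lum": 0.005, "Dcn": 0.005, "Col1a1": 0.004, "Gjb2": 0.003,
        "Cdh11": 0.002,
    },
    "endothelial": {
        "Vwf": 0.005, "Esam": 0.004, "Cdh5": 0.004, "Ecmn": 0.003,
    },
}

_SUBTYPE_MARKERS: dict[str, dict[str, float]] = {
    "alpha-astrocyte": {
        "Sparcl1": 0.003, "Mdfic": 0.002, "Efemp1": 0.002, "Oat": 0.002,
        "Gad2": 0.002,
    },
    "beta-astrocyte": {
        "Slc22a8": 0.003, "Shox2": 0.002, "Lgals1": 0.002, "Mlf1": 0.002,
    },
    "gamma-astrocyte": {
        "Gfap": 0.004, "Aqp4": 0.003, "Slc1a3": 0.003, "Bcan": 0.002,
        "Nkain4": 0.002,
    },
    "alpha-microglia": {
        "C1qa": 0.004, "C1qb": 0.003, "C1qc": 0.003,
    },
    "beta-microglia": {
        "RT1-Da": 0.004, "RT1-Db1": 0.003, "RT1-Ba": 0.003,
    },
}

# Housekeeping modules expressed in every type; only differential between the
# two pinealocyte subtypes (planted alpha modules).
_HOUSEKEEPING_SHARES: dict[str, float] = {
    **{g: 0.0015 for g in OXPHOS_GENES},
    **{g: 0.0015 for g in RIBO_GENES},
}

_MARKER_RESIDUAL_SHARE = 2e-6  # marker weight outside its target type


def _named_genes() -> list[str]:
    names: list[str] = []
    for shares in _FAMILY_MARKERS.values():
        names.extend(shares)
    for shares in _SUBTYPE_MARKERS.values():
        names.extend(shares)
    names.extend(_HOUSEKEEPING_SHARES)
    seen: set[str] = set()
    out = []
    for n in names:
        if n not in seen:
            seen.add(n)
            out.append(n)
    return out


def default_pineal_config(
    n_cells: int,
    seed: int,
    *,
    n_genes: int = 2000,
    ambient_fraction: float = 0.02,
    doublet_rate: float = 0.015,
    proportions: dict[str, float] | None = None,
    n_night_effects: int = 400,
    conditions: tuple[str, str] = ("day", "night"),
    seed_offset: int = 0,
) -> SimConfig:
    """Build the default nine-type pineal-gland configuration.

    Proportions follow the reported composition (pinealocytes 90% at a 5:95
    alpha:beta split, astrocytes 7% split 85/7/8, microglia 1% split 64/36,
    VLMCs 2%, endothelial cells 0.1%).  Alpha-pinealocytes carry the four
    planted modules relative to beta-pinealocytes: Asmt x3.4, an 8-gene OxPhos
    program x2.3, a 20-gene ribosomal program x(1/8.2) and the four G-protein
    gamma-subunit genes x(1/5.4).  A night-condition effect set touches mostly
    pinealocytes (``n_night_effects`` genes at folds 2-8, both directions),
    with smaller effect sets in alpha-astrocytes and VLMCs.

    ``proportions`` may override the per-type shares (values renormalized).
    Raises ``ValueError`` when ``n_cells`` cannot represent the rarest type
    with at least 2 expected cells.
    """
    props = dict(proportions or PINEAL_PROPORTIONS)
    total = sum(props.values())
    props = {k: v / total for k, v in props.items()}
    rarest_name, rarest = min(props.items(), key=lambda kv: kv[1])
    if n_cells * rarest > 0 and n_cells * rarest < 2 - 1e-9:
        raise ValueError(
            f"n_cells={n_cells} expects fewer than 2 cells of the rarest type "
            f"({rarest_name}, {100 * rarest:.2g}%); increase n_cells to at least "
            f"{int(np.ceil(2 / rarest))}"
        )

    rng = np.random.default_rng(seed + seed_offset)
    named = _named_genes()
    n_background = n_genes - len(named)
    if n_background < 200:
        raise ValueError(f"n_genes={n_genes} leaves too few background genes")
    background = [f"Gene{i:04d}" for i in range(1, n_background + 1)]
    gene_ids = named + background
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # Shared background expression: lognormal weights normalized to sum 1.
    bg_weights = rng.lognormal(mean=0.0, sigma=1.1, size=n_background)
    bg_weights /= bg_weights.sum()

    def base_profile() -> np.ndarray:
        w = np.full(n_genes, _MARKER_RESIDUAL_SHARE)
        w[len(named):] = bg_weights
        for g, share in _HOUSEKEEPING_SHARES.items():
            w[gene_index[g]] = share
        return w

    specs: list[CellTypeSpec] = []
    program_rows: list[dict] = []
    for name, prop in props.items():
        fam = family_of(name)
        w = base_profile()
        programs: list[GeneProgram] = []

        def apply(pname: str, shares: dict[str, float], mult: float = 1.0) -> None:
            genes = tuple(shares)
            for g, share in shares.items():
                w[gene_index[g]] = share * mult
            enrich = mult * np.mean(
                [share / _MARKER_RESIDUAL_SHARE for share in shares.values()]
            )
            programs.append(GeneProgram(pname, genes, float(enrich)))
            for g in genes:
                program_rows.append(
                    {"program": pname, "gene": g, "cell_type": name,
                     "multiplier": shares[g] * mult / _MARKER_RESIDUAL_SHARE}
                )

        if fam in _FAMILY_MARKERS:
            apply(f"{fam}-markers", _FAMILY_MARKERS[fam])
        if name in _SUBTYPE_MARKERS:
            apply(f"{name}-markers", _SUBTYPE_MARKERS[name])

        if name == "alpha-pinealocyte":
            # Planted subtype modules, multipliers relative to beta.
            for pname, genes, fold in (
                ("Asmt", ("Asmt",), ASMT_FOLD),
                ("OxPhos", tuple(OXPHOS_GENES), OXPHOS_FOLD),
                ("ribosomal", tuple(RIBO_GENES), RIBO_FOLD),
                ("Ggamma", tuple(GNG_GENES), GNG_FOLD),
            ):
                for g in genes:
                    w[gene_index[g]] *= fold
                programs.append(GeneProgram(f"alpha-{pname}", genes, float(fold)))
                for g in genes:
                    program_rows.append(
                        {"program": f"alpha-{pname}", "gene": g,
                         "cell_type": name, "multiplier": fold}
                    )
        specs.append(
            CellTypeSpec(name=name, proportion=prop, baseline=w / w.sum(),
                         programs=programs)
        )

    # Night effect sets: mostly pinealocytes, smaller sets elsewhere.
    pineal_types = tuple(n for n in props if family_of(n) == "pinealocyte")
    effects: list[ConditionEffect] = []
    if pineal_types:
        effects.append(ConditionEffect("Aanat", pineal_types, 8.0))

    def draw_effects(targets: tuple[str, ...], k: int) -> None:
        if not targets or k <= 0:
            return
        chosen = rng.choice(background, size=min(k, len(background)), replace=False)
        folds = np.exp(rng.uniform(np.log(2.0), np.log(8.0), size=len(chosen)))
        up = rng.random(len(chosen)) < 0.6
        for g, f, u in zip(chosen, folds, up):
            effects.append(ConditionEffect(str(g), targets, float(f if u else 1.0 / f)))

    draw_effects(pineal_types, n_night_effects)
    if "alpha-astrocyte" in props:
        draw_effects(("alpha-astrocyte",), 80)
    if "VLMC" in props:
        draw_effects(("VLMC",), 10)

    cfg = SimConfig(
        n_cells=n_cells,
        gene_ids=gene_ids,
        cell_types=specs,
        condition_effects=effects,
        conditions=conditions,
        ambient_fraction=ambient_fraction,
        doublet_rate=doublet_rate,
        seed=seed,
    )
    cfg.validate()
    cfg._program_rows = program_rows  # type: ignore[attr-defined]
    return cfg


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _effect_matrix(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-type night fold vector e_{v,g} (1 everywhere in the day)."""
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    out = {t.name: np.ones(config.n_genes) for t in config.cell_types}
    for eff in config.condition_effects:
        gi = gene_index.get(eff.gene)
        if gi is None:
            raise ValueError(f"condition effect on unknown gene {eff.gene}")
        for t in eff.target_types:
            if t not in out:
                raise ValueError(f"condition effect targets unknown type {t}")
            out[t][gi] = eff.fold
    return out


def simulate(config: SimConfig) -> tuple["CountMatrix", GroundTruth]:
    """Draw one count matrix plus ground truth from ``config``.

    Deterministic: the same config (including seed) yields an identical
    dataset.  Returns a genes x cells :class:`~pinealsc.io_qc.CountMatrix`
    with randomized column order.
    """
    from .io_qc import CountMatrix  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    type_names = [t.name for t in config.cell_types]
    props = np.array([t.proportion for t in config.cell_types])
    profiles = np.stack([t.baseline for t in config.cell_types])  # types x genes
    night_folds = _effect_matrix(config)
    fold_mat = np.stack([night_folds[t] for t in type_names])
    a = config.ambient_fraction
    ambient = config.pinealocyte_profile() if a > 0 else np.zeros(config.n_genes)

    n_doublets = int(round(config.doublet_rate * n))
    n_singlets = n - n_doublets

    def draw_rates(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        ti = rng.choice(len(type_names), size=size, p=props)
        cond = rng.choice(2, size=size)  # 0 = day, 1 = night
        depth = rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=size)
        p = profiles[ti]
        p = np.where(cond[:, None] == 1, p * fold_mat[ti], p)
        rates = depth[:, None] * ((1.0 - a) * p + a * ambient[None, :])
        return ti, cond, depth, rates

    ti_s, cond_s, depth_s, rates_s = draw_rates(n_singlets)
    rows = [
        {"cell_type": type_names[t], "type_a": type_names[t], "type_b": "",
         "condition": config.conditions[c], "is_doublet": False,
         "library_size": float(d)}
        for t, c, d in zip(ti_s, cond_s, depth_s)
    ]
    rate_blocks = [rates_s]

    if n_doublets:
        # Doublets: both parents drawn at the cell's condition, rates averaged.
        ti_a, cond_d, depth_a, rates_a = draw_rates(n_doublets)
        ti_b = rng.choice(len(type_names), size=n_doublets, p=props)
        depth_b = rng.lognormal(config.depth_log_mean, config.depth_log_sd,
                                size=n_doublets)
        p_b = profiles[ti_b]
        p_b = np.where(cond_d[:, None] == 1, p_b * fold_mat[ti_b], p_b)
        rates_b = depth_b[:, None] * ((1.0 - a) * p_b + a * ambient[None, :])
        rate_blocks.append(0.5 * (rates_a + rates_b))
        for t1, t2, c, d1, d2 in zip(ti_a, ti_b, cond_d, depth_a, depth_b):
            rows.append(
                {"cell_type": f"{type_names[t1]}+{type_names[t2]}",
                 "type_a": type_names[t1], "type_b": type_names[t2],
                 "condition": config.conditions[c], "is_doublet": True,
                 "library_size": float(0.5 * (d1 + d2))}
            )

    rates = np.vstack(rate_blocks)
    counts = rng.poisson(rates).astype(np.int64)  # cells x genes

    order = rng.permutation(n)
    counts = counts[order]
    cells = pd.DataFrame([rows[i] for i in order])
    cells.index = pd.Index([f"cell_{i:05d}" for i in range(n)], name="barcode")
    cells["family"] = [
        "doublet" if d else family_of(t)
        for t, d in zip(cells["cell_type"], cells["is_doublet"])
    ]

    matrix = CountMatrix(
        counts=sp.csr_matrix(counts.T),
        gene_ids=pd.Index(config.gene_ids, name="gene"),
        cell_ids=cells.index.copy(),
    )

    gene_effects = pd.DataFrame(
        [
            {"gene": e.gene, "cell_type": t, "fold": e.fold}
            for e in config.condition_effects
            for t in e.target_types
        ],
        columns=["gene", "cell_type", "fold"],
    )
    program_rows = getattr(config, "_program_rows", None)
    programs = pd.DataFrame(
        program_rows or
        [
            {"program": p.name, "gene": g, "cell_type": t.name,
             "multiplier": p.enrichment}
            for t in config.cell_types for p in t.programs for g in p.genes
        ],
        columns=["program", "gene", "cell_type", "multiplier"],
    )
    return matrix, GroundTruth(cells=cells, gene_effects=gene_effects,
                               programs=programs)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_dataset(matrix, truth: GroundTruth | None, directory: str | Path,
                  config: SimConfig | None = None) -> dict:
    """Write a dataset as MatrixMarket + TSV sidecars; returns the manifest.

    Emits ``matrix.mtx`` (coordinate integer), ``genes.tsv``, ``barcodes.tsv``,
    ``cell_metadata.tsv`` plus ``gene_effects.tsv`` / ``programs.tsv`` when
    ground truth is given, and ``config.json`` when the config is given.  The
    layout round-trips losslessly through :func:`pinealsc.io_qc.read_counts`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(matrix.counts),
                     field="integer")
    files["matrix"] = "matrix.mtx"
    pd.Series(matrix.gene_ids).to_csv(directory / "genes.tsv", sep="\t",
                                      index=False, header=False)
    files["genes"] = "genes.tsv"
    pd.Series(matrix.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    files["barcodes"] = "barcodes.tsv"

    if truth is not None:
        truth.cells.to_csv(directory / "cell_metadata.tsv", sep="\t")
        files["cell_metadata"] = "cell_metadata.tsv"
        truth.gene_effects.to_csv(directory / "gene_effects.tsv", sep="\t",
                                  index=False)
        files["gene_effects"] = "gene_effects.tsv"
        truth.programs.to_csv(directory / "programs.tsv", sep="\t", index=False)
        files["programs"] = "programs.tsv"
    if config is not None:
        with open(directory / "config.json", "w") as fh:
            json.dump(config.to_jsonable(), fh, sort_keys=True)
        files["config"] = "config.json"

    manifest = {
        "files": files,
        "n_genes": int(matrix.counts.shape[0]),
        "n_cells": int(matrix.counts.shape[1]),
        "nnz": int(matrix.counts.nnz),
        "seed": None if config is None else config.seed,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
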