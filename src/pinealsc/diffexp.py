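"""Condition-contrast differential expression with a composite decision rule.

Per cell type, every gene is tested between conditions (day vs night, or drug
vs vehicle) with the Wilcoxon rank-sum test on normalized counts.  A gene is
called differentially expressed when all four criteria hold:

* p < 0.01 (FDR-adjusted by default; the raw-p reading is supported),
* detected in at least 15% of cells in either group,
* pseudocounted fold change >= 2.0, where
  FC = (0.01 + mean_a) / (0.01 + mean_b), reported direction-free as
  max(FC, 1/FC),
* effect size |Cohen's d| >= 0.35, with the pooled standard deviation
  sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).

The joint rule suppresses false positives from technical noise in low
expressing genes.  Ambient-contamination genes (by default Aanat, whose
transcripts leak from lysed pinealocytes into every droplet) are excluded
from testing in non-pinealocyte cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix
from .simulate import family_of

__all__ = [
    "GroupStats",
    "DECriteria",
    "GeneGroup",
    "fold_change",
    "reported_fold",
    "cohens_d",
    "bh_adjust",
    "de_test",
    "composite_de_table",
    "ambient_exclusion",
    "group_comparison",
    "de_overlap",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary of one gene in one (cell type, condition) group."""

    mean: float
    sd: float
    n: int
    detection: float = 0.0

    @classmethod
    def from_values(cls, x: np.ndarray) -> "GroupStats":
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            raise ValueError("empty sample")
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return cls(mean=float(x.mean()), sd=sd, n=int(x.size),
                   detection=float((x > 0).mean()))


@dataclass(frozen=True)
class DECriteria:
    """Thresholds of the composite DE decision rule."""

    p_threshold: float = 0.01
    min_detection: float = 0.15
    fc_threshold: float = 2.0
    d_threshold: float = 0.35
    pseudocount: float = 0.01
    fdr_alpha: float = 0.05
    p_is_adjusted: bool = True

    def __post_init__(self) -> None:
        for name in ("p_threshold", "min_detection", "fc_threshold",
                     "d_threshold", "pseudocount", "fdr_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GeneGroup:
    """A named gene set whose per-cell counts are pooled for comparison."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene group {self.name} is empty")


def fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.01) -> float:
    """Pseudocounted ratio (pseudocount + mean_a) / (pseudocount + mean_b)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    return (pseudocount + mean_a) / (pseudocount + mean_b)


def reported_fold(ratio: float) -> float:
    """Direction-free fold: max of the ratio and its inverse."""
    return max(ratio, 1.0 / ratio)


def cohens_d(stats_a: GroupStats, stats_b: GroupStats) -> float:
    """Standardized mean difference with the pooled standard deviation.

    When the pooled sd is zero: equal means give 0, unequal means give a
    signed infinity (a degenerate perfectly-separated case that passes any
    magnitude threshold).
    """
    n_a, n_b = stats_a.n, stats_b.n
    if n_a + n_b < 3:
        raise ValueError("need at least 3 observations in total")
    pooled_var = ((n_a - 1) * stats_a.sd ** 2 + (n_b - 1) * stats_b.sd ** 2) \
        / (n_a + n_b - 2)
    pooled_sd = float(np.sqrt(pooled_var))
    diff = stats_a.mean - stats_b.mean
    if pooled_sd == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return diff / pooled_sd


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_p(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene; xa, xb are genes x cells blocks."""
    res = scipy.stats.mannwhitneyu(xa, xb, axis=1, method="asymptotic",
                                   use_continuity=True)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)  # all-tied genes -> p = 1


def composite_de_table(xa: np.ndarray, xb: np.ndarray, genes: pd.Index,
                       criteria: DECriteria | None = None) -> pd.DataFrame:
    """Apply the composite rule to two expression blocks (genes x cells).

    Group ``a`` is the night/drug condition, ``b`` day/vehicle.  Returns one
    row per gene with group statistics, fold change, Cohen's d, raw and
    BH-adjusted p, the four criterion flags, the final ``de`` call and the
    direction (``a-up`` / ``b-up``).
    """
    criteria = criteria or DECriteria()
    n_a, n_b = xa.shape[1], xb.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need cells")

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = xa.std(axis=1, ddof=1) if n_a > 1 else np.zeros_like(mean_a)
    sd_b = xb.std(axis=1, ddof=1) if n_b > 1 else np.zeros_like(mean_b)
    det_a = (xa > 0).mean(axis=1)
    det_b = (xb > 0).mean(axis=1)

    pc = criteria.pseudocount
    ratio = (pc + mean_a) / (pc + mean_b)
    fold = np.maximum(ratio, 1.0 / ratio)

    pooled = np.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2)
                     / max(n_a + n_b - 2, 1))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / pooled
    degenerate = pooled == 0
    dd = diff[degenerate]
    d[degenerate] = np.where(dd > 0, np.inf, np.where(dd < 0, -np.inf, 0.0))

    p_raw = _ranksum_p(xa, xb)
    p_adj = bh_adjust(p_raw)
    p_used = p_adj if criteria.p_is_adjusted else p_raw

    pass_p = p_used < criteria.p_threshold
    pass_det = np.maximum(det_a, det_b) >= criteria.min_detection
    pass_fc = fold >= criteria.fc_threshold
    pass_d = np.abs(d) >= criteria.d_threshold
    de = pass_p & pass_det & pass_fc & pass_d

    return pd.DataFrame(
        {
            "mean_a": mean_a, "mean_b": mean_b, "sd_a": sd_a, "sd_b": sd_b,
            "n_a": n_a, "n_b": n_b, "detection_a": det_a, "detection_b": det_b,
            "ratio": ratio, "fold_change": fold, "cohens_d": d,
            "p": p_raw, "p_adjusted": p_adj,
            "pass_p": pass_p, "pass_detection": pass_det,
            "pass_fold": pass_fc, "pass_effect": pass_d, "de": de,
            "direction": np.where(diff >= 0, "a-up", "b-up"),
        },
        index=genes,
    )


def ambient_exclusion(cell_types, default: tuple[str, ...] = ("Aanat",)
                      ) -> dict[str, list[str]]:
    """Per-cell-type exclusion lists for ambient pinealocyte transcripts.

    Pinealocyte markers leak into every droplet at low uniform levels when
    pinealocytes lyse during dissociation; rhythmic ones (Aanat) would then
    appear differentially expressed in every cell type.  They are therefore
    excluded from DE testing in non-pinealocyte types only.
    """
    out: dict[str, list[str]] = {}
    for t in cell_types:
        out[t] = [] if family_of(t) == "pinealocyte" else list(default)
    return out


def de_test(m: NormalizedMatrix, annotation: pd.Series, cell_type: str,
            condition: pd.Series, criteria: DECriteria | None = None,
            exclusions: list[str] | None = None,
            condition_order: tuple[str, str] | None = None) -> pd.DataFrame:
    """Composite-rule DE for one cell type between two conditions.

    ``annotation`` and ``condition`` are per-cell Series aligned to the
    matrix columns.  All genes are tested (no expression pre-filter) except
    those in ``exclusions``, which are removed before adjustment.  Group
    ``a`` is the second condition of ``condition_order`` (night/drug by
    sorted order when not given).  Raises when either group has fewer than
    3 cells of the type.
    """
    if m.scheme != "per10k":
        raise ValueError("de_test expects per-10k normalized counts")
    criteria = criteria or DECriteria()
    annotation = annotation.reindex(m.cell_ids)
    condition = condition.reindex(m.cell_ids)
    in_type = (annotation == cell_type).to_numpy()
    levels = condition_order or tuple(sorted(condition[in_type].dropna().unique()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    cond_b, cond_a = levels  # a = night/drug (second level)
    mask_a = in_type & (condition == cond_a).to_numpy()
    mask_b = in_type & (condition == cond_b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"{cell_type}: fewer than 3 cells in a condition group "
            f"({cond_a}: {mask_a.sum()}, {cond_b}: {mask_b.sum()})"
        )

    keep = np.ones(len(m.gene_ids), dtype=bool)
    if exclusions:
        keep = ~m.gene_ids.isin(exclusions)
    xa = m.values[np.ix_(keep, mask_a)]
    xb = m.values[np.ix_(keep, mask_b)]
    table = composite_de_table(xa, xb, m.gene_ids[keep], criteria)
    table.insert(0, "cell_type", cell_type)
    table["direction"] = table["direction"].map(
        {"a-up": f"{cond_a}-up", "b-up": f"{cond_b}-up"}
    )
    return table


def group_comparison(m: NormalizedMatrix, annotation: pd.Series,
                     group: GeneGroup, type_a: str, type_b: str,
                     pseudocount: float = 0.01) -> dict:
    """Pooled gene-group comparison between two cell types.

    Sums normalized counts over the group's genes per cell, then reports each
    type's mean pooled expression, their pseudocounted ratio (a over b) and
    the Wilcoxon rank-sum p between the per-cell pooled values.
    """
    if m.scheme != "per10k":
        raise ValueError("group_comparison expects per-10k normalized counts")
    present = [g for g in group.genes if g in m.gene_ids]
    if not present:
        raise ValueError(f"no genes of group {group.name} in the matrix")
    annotation = annotation.reindex(m.cell_ids)
    idx = m.gene_ids.get_indexer(pd.Index(present))
    pooled = m.values[idx].sum(axis=0)
    va = pooled[(annotation == type_a).to_numpy()]
    vb = pooled[(annotation == type_b).to_numpy()]
    if va.size == 0 or vb.size == 0:
        raise ValueError(f"no cells of type {type_a!r} or {type_b!r}")
    ratio = fold_change(float(va.mean()), float(vb.mean()), pseudocount)
    p = float(scipy.stats.mannwhitneyu(va, vb, method="asymptotic",
                                       use_continuity=True).pvalue)
    return {
        "group": group.name, "genes_used": present,
        "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
        "n_a": int(va.size), "n_b": int(vb.size),
        "ratio": ratio, "fold": reported_fold(ratio), "p": p,
    }


def de_overlap(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap table of named DE gene sets.

    One row per ordered pair with |A|, |B|, |A intersect B|, |A \\ B| and the
    percentage of A also in B; a final row gives the intersection of all sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least two named sets")
    names = list(sets)
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = sets[a] & sets[b]
            rows.append({
                "set_a": a, "set_b": b, "size_a": len(sets[a]),
                "size_b": len(sets[b]), "intersection": len(inter),
                "only_a": len(sets[a] - sets[b]),
                "pct_a_in_b": 100.0 * len(inter) / len(sets[a]) if sets[a] else 0.0,
            })
    full = set.intersection(*(set(s) for s in sets.values()))
    rows.append({"set_a": "ALL", "set_b": "ALL",
                 "size_a": sum(len(s) for s in sets.values()), "size_b": 0,
                 "intersection": len(full), "only_a": 0, "pct_a_in_b": np.nan})
    return pd.DataFrame(rows)
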