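"""Per-cluster marker discovery and reference-panel annotation.

Markers are found one-vs-rest with either the Wilcoxon rank-sum test
(``wilcox`` mode) or a ROC classifier (``roc`` mode, classification power
2*|AUC - 0.5|).  Clusters are annotated against a panel of established
cell-type markers: pinealocytes (Tph1, Asmt, Sag), astrocytes (Aldh1a1,
S100b, Tnfrsf21), microglia (Aif1, Lyz2), VLMCs (Lum, Dcn, Col1a1, Gjb2) and
endothelial cells (Vwf, Esam, Cdh5, Ecmn).  Subtypes within a family are
named alpha/beta(/gamma) by descending size, except where a subtype-defining
gene is configured (alpha-pinealocytes are the rare Asmt-high cluster, not
the largest one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import NormalizedMatrix

__all__ = [
    "MarkerResult",
    "ReferencePanel",
    "DEFAULT_PANEL",
    "DEFAULT_SUBTYPE_GENES",
    "wilcoxon_rank_sum",
    "roc_power",
    "find_markers",
    "annotate_clusters",
]

GREEK = ("alpha", "beta", "gamma", "delta", "epsilon")


@dataclass(frozen=True)
class MarkerResult:
    gene: str
    cluster: object
    mean_in: float
    mean_out: float
    detection_in: float
    detection_out: float
    p: float | None = None
    auc: float | None = None
    power: float | None = None


@dataclass
class ReferencePanel:
    """Mapping cell-type name -> marker gene list."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("empty reference panel")
        for t, genes in self.markers.items():
            if not genes:
                raise ValueError(f"panel type {t} has no genes")

    def restricted_to(self, universe: pd.Index) -> "ReferencePanel":
        kept: dict[str, list[str]] = {}
        for t, genes in self.markers.items():
            present = [g for g in genes if g in universe]
            missing = set(genes) - set(present)
            if missing:
                warnings.warn(
                    f"panel type {t}: genes absent from universe: {sorted(missing)}"
                )
            if present:
                kept[t] = present
        if not kept:
            raise ValueError("no panel gene present in the matrix")
        return ReferencePanel(kept)


DEFAULT_PANEL = ReferencePanel({
    "pinealocyte": ["Tph1", "Asmt", "Sag"],
    "astrocyte": ["Aldh1a1", "S100b", "Tnfrsf21"],
    "microglia": ["Aif1", "Lyz2"],
    "VLMC": ["Lum", "Dcn", "Col1a1", "Gjb2"],
    "endothelial": ["Vwf", "Esam", "Cdh5", "Ecmn"],
})

# Subtype-defining genes override size-based naming within a family:
# the subtype whose cluster has the highest mean expression of the gene
# receives that name.
DEFAULT_SUBTYPE_GENES: dict[str, dict[str, str]] = {
    "pinealocyte": {"alpha": "Asmt"},
}


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when n_x + n_y <= 10 with no ties, otherwise the
    normal approximation with tie and continuity corrections.  Returns
    (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 10 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method, use_continuity=True)
    p = float(res.pvalue)
    return float(res.statistic), (p if np.isfinite(p) else 1.0)


def roc_power(x_in, x_out) -> tuple[float, float]:
    """AUC = P(in > out) + 0.5 P(tie), and classification power 2|AUC - 0.5|."""
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if x_in.size == 0 or x_out.size == 0:
        raise ValueError("empty sample")
    ranks = scipy.stats.rankdata(np.concatenate([x_in, x_out]))
    r_in = ranks[: x_in.size].sum()
    u = r_in - x_in.size * (x_in.size + 1) / 2.0
    auc = u / (x_in.size * x_out.size)
    return float(auc), float(2.0 * abs(auc - 0.5))


def _auc_rows(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Row-wise AUC for genes x cells blocks (average ranks handle ties)."""
    n_in, n_out = x_in.shape[1], x_out.shape[1]
    ranks = scipy.stats.rankdata(np.hstack([x_in, x_out]), axis=1)
    r_in = ranks[:, :n_in].sum(axis=1)
    return (r_in - n_in * (n_in + 1) / 2.0) / (n_in * n_out)


def find_markers(m: NormalizedMatrix, labels: pd.Series, cluster,
                 mode: str = "wilcox", min_detection: float = 0.10
                 ) -> pd.DataFrame:
    """One-vs-rest marker table for one cluster.

    Tests genes detected in at least ``min_detection`` of cells in either
    group (set 0 to test everything); ranks by p (``wilcox``) or by
    classification power (``roc``).  Means are of un-logged per-10k counts.
    """
    if mode not in ("wilcox", "roc"):
        raise ValueError(f"unknown mode {mode!r}")
    if m.scheme != "per10k":
        raise ValueError("find_markers expects per-10k normalized counts")
    labels = labels.reindex(m.cell_ids)
    in_mask = (labels == cluster).to_numpy()
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster!r} has no cells")
    if in_mask.sum() < 3:
        warnings.warn(f"cluster {cluster!r} has < 3 cells; results are weak")
    out_mask = (~in_mask) & labels.notna().to_numpy()

    x_in, x_out = m.values[:, in_mask], m.values[:, out_mask]
    det_in, det_out = (x_in > 0).mean(axis=1), (x_out > 0).mean(axis=1)
    tested = np.maximum(det_in, det_out) >= min_detection
    x_in, x_out = x_in[tested], x_out[tested]

    table = pd.DataFrame(
        {
            "cluster": cluster,
            "mean_in": x_in.mean(axis=1), "mean_out": x_out.mean(axis=1),
            "detection_in": det_in[tested], "detection_out": det_out[tested],
        },
        index=m.gene_ids[tested],
    )
    auc = _auc_rows(x_in, x_out)
    table["auc"] = auc
    table["power"] = 2.0 * np.abs(auc - 0.5)
    if mode == "wilcox":
        res = scipy.stats.mannwhitneyu(x_in, x_out, axis=1,
                                       method="asymptotic", use_continuity=True)
        p = np.asarray(res.pvalue, dtype=float)
        table["p"] = np.where(np.isfinite(p), p, 1.0)
        table = table.sort_values(["p", "power"], ascending=[True, False],
                                  kind="mergesort")
    else:
        table = table.sort_values("power", ascending=False, kind="mergesort")
    table.index.name = "gene"
    return table


def annotate_clusters(m: NormalizedMatrix, labels: pd.Series,
                      panel: ReferencePanel = DEFAULT_PANEL,
                      subtype_genes: dict[str, dict[str, str]] | None = None,
                      margin: float = 0.1, min_expr: float = 1.0,
                      manual: dict | None = None) -> pd.DataFrame:
    """Assign a panel cell type to each cluster.

    Cluster means of log1p per-10k expression are z-scored per gene across
    clusters; a cluster gets the type whose panel genes have the highest mean
    z-score.  A type is only eligible for a cluster when the cluster's mean
    per-10k expression pooled over the type's panel genes reaches
    ``min_expr`` — z-scores of essentially unexpressed genes are noise.  A
    top-two score margin below ``margin`` yields "unassigned".
    Clusters sharing a family are suffixed alpha/beta/gamma by descending
    size, unless ``subtype_genes`` names a subtype-defining gene (then that
    subtype is the cluster with the highest mean expression of the gene).
    ``manual`` maps cluster label -> type name and overrides scoring (the
    endothelial-style manual identity assignment).

    Returns a DataFrame indexed by cluster with columns ``family``, ``type``,
    ``score``, ``margin``, ``n_cells``.
    """
    if m.scheme != "per10k":
        raise ValueError("annotate_clusters expects per-10k normalized counts")
    if subtype_genes is None:
        subtype_genes = DEFAULT_SUBTYPE_GENES
    panel = panel.restricted_to(m.gene_ids)
    labels = labels.reindex(m.cell_ids)
    clusters = sorted(labels.dropna().unique(), key=str)
    if not clusters:
        raise ValueError("no labeled cells")

    log_vals = np.log1p(m.values)
    means = np.column_stack([
        log_vals[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters
    ])  # genes x clusters
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (means - mu) / sd
    z[~np.isfinite(z)] = 0.0
    zdf = pd.DataFrame(z, index=m.gene_ids, columns=clusters)

    raw_means = np.column_stack([
        m.values[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters
    ])
    mdf = pd.DataFrame(raw_means, index=m.gene_ids, columns=clusters)

    scores = pd.DataFrame(
        {t: zdf.loc[genes].mean(axis=0) for t, genes in panel.markers.items()}
    )  # clusters x types
    expressed = pd.DataFrame(
        {t: mdf.loc[genes].mean(axis=0) >= min_expr
         for t, genes in panel.markers.items()}
    )
    scores = scores.where(expressed, -np.inf)
    rows = []
    for c in clusters:
        s = scores.loc[c].sort_values(ascending=False)
        gap = float(s.iloc[0] - s.iloc[1]) if len(s) > 1 else float("inf")
        if not np.isfinite(s.iloc[0]):
            rows.append({"cluster": c, "family": "unassigned",
                         "score": float("nan"), "margin": float("nan"),
                         "n_cells": int((labels == c).sum())})
            continue
        if manual and c in manual:
            fam, sc = manual[c], float("nan")
        elif gap < margin:
            fam, sc = "unassigned", float(s.iloc[0])
        else:
            fam, sc = s.index[0], float(s.iloc[0])
        rows.append({"cluster": c, "family": fam, "score": sc, "margin": gap,
                     "n_cells": int((labels == c).sum())})
    out = pd.DataFrame(rows).set_index("cluster")

    # Subtype naming within families with more than one cluster.
    type_names = {}
    for fam, group in out.groupby("family"):
        members = group.index.tolist()
        if fam == "unassigned" or len(members) == 1:
            for c in members:
                type_names[c] = fam
            continue
        remaining = sorted(members, key=lambda c: (-out.loc[c, "n_cells"], str(c)))
        assigned: dict[str, object] = {}
        for sub, gene in (subtype_genes.get(fam) or {}).items():
            if gene not in m.gene_ids:
                warnings.warn(f"subtype gene {gene} absent; falling back to size")
                continue
            expr = m.gene_row(gene)
            best = max(remaining,
                       key=lambda c: expr[(labels == c).to_numpy()].mean())
            assigned[sub] = best
            remaining.remove(best)
        free = [g for g in GREEK if g not in assigned]
        for sub, c in zip(free, remaining):
            assigned[sub] = c
        for sub, c in assigned.items():
            type_names[c] = f"{sub}-{fam}"
    out["type"] = [type_names[c] for c in out.index]
    return out[["family", "type", "score", "margin", "n_cells"]]
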