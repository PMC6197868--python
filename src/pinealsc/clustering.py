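"""PCA, shared-nearest-neighbor graph clustering and cluster post-processing.

Cells are embedded by exact PCA of the scaled highly-variable-gene matrix,
connected in a shared-nearest-neighbor (SNN) graph whose edge weights are
Jaccard overlaps of k-nearest-neighbor sets in PC space, and partitioned by
modularity maximization (Leiden with the RB-configuration objective, a
deterministic Louvain-family optimizer).  Raw communities are consolidated:
two clusters merge when no gene passes the composite DE decision rule
between them, mirroring the practice of merging algorithmic sub-clusters of
one biological population.  Putative doublets — cells expressing
moderate-to-high levels of markers specific to two different clusters — are
flagged and excluded.  A dendrogram over cluster mean expression profiles
summarizes cluster relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .diffexp import DECriteria, composite_de_table
from .preprocess import HVGSelection, NormalizedMatrix

__all__ = [
    "PCAModel",
    "SNNGraph",
    "ClusterModel",
    "ConsolidationRule",
    "run_pca",
    "build_snn",
    "find_communities",
    "consolidate",
    "exclude_doublets",
    "cluster_tree",
    "cluster_proportions",
]


@dataclass
class PCAModel:
    components: np.ndarray      # genes x k orthonormal loadings
    cell_scores: np.ndarray     # cells x k
    variance_explained: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index

    @property
    def k_used(self) -> int:
        return self.cell_scores.shape[1]


@dataclass
class SNNGraph:
    weights: sp.csr_matrix      # symmetric, zero diagonal, weights in (0, 1]
    cell_ids: pd.Index
    knn_k: int
    prune: float


@dataclass
class ClusterModel:
    """Cluster labels with their consolidation history."""

    raw_labels: pd.Series                  # per cell, raw community id
    consolidation_map: dict                # raw id -> final id
    labels: pd.Series                      # per cell, final id (NaN = excluded)
    excluded: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    dendrogram: object | None = None       # scipy linkage over final clusters
    dendrogram_leaves: list | None = None

    def final_clusters(self) -> list:
        return sorted(self.labels.dropna().unique(), key=str)


@dataclass
class ConsolidationRule:
    """Merge clusters with no composite-rule DE gene between them.

    ``manual_merges`` (raw id -> target raw id) overrides the test for the
    listed pairs.  ``max_cells_per_group`` caps the per-cluster sample used
    by the pairwise tests, for speed on very large clusters.
    """

    criteria: DECriteria = field(default_factory=DECriteria)
    manual_merges: dict | None = None
    max_cells_per_group: int = 1000
    seed: int = 0


def run_pca(m: NormalizedMatrix, k: int, hvg: HVGSelection | None = None
            ) -> PCAModel:
    """Exact-SVD PCA of the scaled matrix; sign-fixed, hence deterministic.

    ``m`` must be the gene-scaled (z-scored) matrix; when ``hvg`` is given the
    matrix is first restricted to the selected genes.  Each component's sign
    is fixed so its largest-magnitude gene loading is positive.
    """
    if m.scheme != "scaled":
        raise ValueError("run_pca expects the scaled matrix")
    if hvg is not None:
        genes = [g for g in hvg.genes if g in m.gene_ids]
        m = m.subset_genes(genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(m.values.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(m.values.shape)}")
    x = m.values.T  # cells x genes, already column-centered by scaling
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    comps = vt[:k].T                      # genes x k
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    comps = comps * flip
    scores = (u[:, :k] * s[:k]) * flip
    total_var = float((s ** 2).sum())
    var_exp = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(components=comps, cell_scores=scores,
                    variance_explained=var_exp, gene_ids=m.gene_ids,
                    cell_ids=m.cell_ids)


def build_snn(p: PCAModel, knn_k: int = 30, prune: float = 1 / 15
              ) -> SNNGraph:
    """Shared-nearest-neighbor graph from PC scores.

    Neighborhoods are the ``knn_k`` Euclidean nearest neighbors in PC space,
    self included; edge(i, j) is the Jaccard overlap of the two neighbor
    sets, dropped when below ``prune``.
    """
    n = p.cell_scores.shape[0]
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be smaller than n_cells={n}")
    nn = NearestNeighbors(n_neighbors=knn_k).fit(p.cell_scores)
    _, idx = nn.kneighbors(p.cell_scores)  # self is its own nearest neighbor
    rows = np.repeat(np.arange(n), knn_k)
    membership = sp.csr_matrix(
        (np.ones(n * knn_k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (membership @ membership.T).tocoo()
    inter = shared.data
    jaccard = inter / (2 * knn_k - inter)
    keep = (jaccard >= prune) & (shared.row != shared.col)
    weights = sp.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    return SNNGraph(weights=weights, cell_ids=p.cell_ids, knn_k=knn_k,
                    prune=prune)


def find_communities(g: SNNGraph, resolution: float = 0.8, seed: int = 0
                     ) -> pd.Series:
    """Modularity-maximizing partition of the SNN graph.

    Uses the Leiden optimizer with the RB-configuration quality function
    (Louvain-family modularity with a resolution parameter); deterministic
    for a fixed seed.  Nodes are canonicalized to sorted cell-id order
    first, so permuting the input cells cannot change any assignment.
    Labels are integers ordered by decreasing community size.
    """
    canon = np.argsort(g.cell_ids)
    weights = g.weights[canon][:, canon]
    coo = sp.triu(weights, k=1).tocoo()
    graph = igraph.Graph(
        n=weights.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    labels = np.empty_like(membership)
    labels[canon] = membership
    order = pd.Series(labels).value_counts().index.tolist()
    relabel = {old: new for new, old in enumerate(order)}
    return pd.Series([relabel[v] for v in labels], index=g.cell_ids,
                     name="raw_cluster")


def _union_find_merge(clusters: list, pairs: list[tuple]) -> dict:
    parent = {c: c for c in clusters}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb, key=str)] = min(ra, rb, key=str)
    roots = sorted({find(c) for c in clusters}, key=str)
    root_id = {r: i for i, r in enumerate(roots)}
    return {c: root_id[find(c)] for c in clusters}


def consolidate(m: NormalizedMatrix, raw_labels: pd.Series,
                rule: ConsolidationRule | None = None) -> ClusterModel:
    """Merge raw communities that show no composite-rule DE gene.

    All cluster pairs are tested with the composite DE rule on per-10k
    counts; pairs with zero passing genes are merged (transitively).  Manual
    merges from the rule are applied unconditionally.  Final labels are
    integers ordered by decreasing cluster size.
    """
    if m.scheme != "per10k":
        raise ValueError("consolidate expects per-10k normalized counts")
    rule = rule or ConsolidationRule()
    raw_labels = raw_labels.reindex(m.cell_ids)
    clusters = sorted(raw_labels.dropna().unique(), key=str)
    rng = np.random.default_rng(rule.seed)

    def group_block(c) -> np.ndarray:
        mask = (raw_labels == c).to_numpy()
        cols = np.flatnonzero(mask)
        if len(cols) > rule.max_cells_per_group:
            cols = np.sort(rng.choice(cols, rule.max_cells_per_group,
                                      replace=False))
        return m.values[:, cols]

    blocks = {c: group_block(c) for c in clusters}
    pairs: list[tuple] = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            if blocks[a].shape[1] < 3 or blocks[b].shape[1] < 3:
                continue
            table = composite_de_table(blocks[a], blocks[b], m.gene_ids,
                                       rule.criteria)
            if not table["de"].any():
                pairs.append((a, b))

    if rule.manual_merges:
        for a, b in rule.manual_merges.items():
            if a not in raw_labels.values and a not in clusters:
                raise ValueError(f"manual merge source {a!r} is not a cluster")
            seen = {a}
            target = b
            while target in rule.manual_merges:
                target = rule.manual_merges[target]
                if target in seen:
                    raise ValueError("cyclic manual merge map")
                seen.add(target)
            pairs.append((a, b))

    cmap = _union_find_merge(clusters, pairs)
    merged = raw_labels.map(cmap)
    order = merged.value_counts().index.tolist()
    relabel = {old: new for new, old in enumerate(order)}
    final = merged.map(relabel)
    cmap = {c: relabel[v] for c, v in cmap.items()}
    return ClusterModel(raw_labels=raw_labels, consolidation_map=cmap,
                        labels=final.rename("cluster"))


def exclude_doublets(m: NormalizedMatrix, model: ClusterModel,
                     markers: dict | None = None, level: float | None = None,
                     ratio_min: float = 5.0, min_detection: float = 0.5,
                     floor_frac: float = 0.25) -> ClusterModel:
    """Flag cells expressing moderate-to-high levels of genes specific to a
    different cluster, and drop them from the labels.

    For every ordered cluster pair (c1, c2) the genes specific to c1
    relative to c2 are those with mean expression at least ``ratio_min``
    times higher in c1 (pseudocounted) and detected in at least
    ``min_detection`` of c1's cells.  A member of c2 whose summed per-10k
    expression of that gene set exceeds ``floor_frac`` times the median sum
    among c1's own members ("moderate-to-high") is a putative doublet.  The
    level-based definition also catches doublets of two subtypes that share
    their family markers and differ only in expression magnitude.

    ``markers`` optionally supplies explicit per-cluster marker gene lists;
    a cell is then flagged when its marker sum exceeds the threshold for two
    or more distinct clusters.  ``level`` replaces the per-pair threshold
    with one fixed value.
    """
    if m.scheme != "per10k":
        raise ValueError("exclude_doublets expects per-10k normalized counts")
    labels = model.labels.reindex(m.cell_ids)
    clusters = model.final_clusters()
    labeled = labels.notna().to_numpy()
    flagged = np.zeros(len(m.cell_ids), dtype=bool)

    if markers is not None:
        over = np.zeros(len(m.cell_ids), dtype=int)
        for c in clusters:
            genes = [g for g in markers.get(c, []) if g in m.gene_ids]
            if not genes:
                continue
            idx = m.gene_ids.get_indexer(pd.Index(genes))
            sums = m.values[idx].sum(axis=0)
            member = (labels == c).to_numpy()
            med = float(np.median(sums[member])) if member.any() else 0.0
            thr = level if level is not None else floor_frac * med
            over += (sums > thr).astype(int)
        flagged = (over >= 2) & labeled
    else:
        member_masks = {c: (labels == c).to_numpy() for c in clusters}
        means = {c: m.values[:, member_masks[c]].mean(axis=1) for c in clusters}
        dets = {c: (m.values[:, member_masks[c]] > 0).mean(axis=1)
                for c in clusters}
        pc = 0.01
        for c1 in clusters:
            for c2 in clusters:
                if c1 == c2 or not member_masks[c2].any():
                    continue
                specific = (means[c1] >= ratio_min * (means[c2] + pc)) \
                    & (dets[c1] >= min_detection)
                if not specific.any():
                    continue
                sums = m.values[specific].sum(axis=0)
                med = float(np.median(sums[member_masks[c1]]))
                # absolute floor of 2 per-10k: a single stray count must
                # never flag a cell
                thr = level if level is not None else max(floor_frac * med, 2.0)
                n_detected = (m.values[specific] > 0).sum(axis=0)
                enough = n_detected >= min(2, int(specific.sum()))
                flagged |= member_masks[c2] & (sums > thr) & enough
        flagged &= labeled

    new_labels = labels.copy()
    new_labels[flagged] = np.nan
    excluded = pd.Series("doublet", index=m.cell_ids[flagged], name="reason")
    return ClusterModel(raw_labels=model.raw_labels,
                        consolidation_map=model.consolidation_map,
                        labels=new_labels, excluded=excluded,
                        dendrogram=model.dendrogram,
                        dendrogram_leaves=model.dendrogram_leaves)


def cluster_tree(m: NormalizedMatrix, model: ClusterModel,
                 hvg: HVGSelection) -> ClusterModel:
    """Average-linkage dendrogram over cluster mean log HVG profiles.

    Distances are Euclidean between the per-cluster mean log1p(per-10k)
    profiles restricted to the highly variable genes.  Attaches the scipy
    linkage matrix and leaf order (lexicographic tie-break via sorted input
    order) to the model.
    """
    if m.scheme != "per10k":
        raise ValueError("cluster_tree expects per-10k normalized counts")
    clusters = model.final_clusters()
    if len(clusters) < 2:
        raise ValueError("need at least 2 final clusters")
    labels = model.labels.reindex(m.cell_ids)
    genes = [g for g in hvg.genes if g in m.gene_ids]
    sub = np.log1p(m.subset_genes(genes).values)
    profiles = np.vstack([
        sub[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters
    ])
    linkage = scipy.cluster.hierarchy.linkage(profiles, method="average",
                                              metric="euclidean")
    leaves = scipy.cluster.hierarchy.leaves_list(linkage)
    model.dendrogram = linkage
    model.dendrogram_leaves = [clusters[i] for i in leaves]
    return model


def tree_to_newick(model: ClusterModel, names: dict | None = None) -> str:
    """Render the cluster dendrogram as a Newick string."""
    if model.dendrogram is None:
        raise ValueError("no dendrogram; run cluster_tree first")
    clusters = model.final_clusters()
    names = names or {c: str(c) for c in clusters}
    tree = scipy.cluster.hierarchy.to_tree(model.dendrogram)

    def render(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[clusters[node.id]]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def cluster_proportions(model: ClusterModel, annotation: pd.DataFrame
                        ) -> pd.DataFrame:
    """Per-type cell counts, percentages of total and within-family shares.

    ``annotation`` is the table from :func:`pinealsc.markers.annotate_clusters`
    (indexed by cluster with ``type`` and ``family`` columns).
    """
    from .simulate import family_of

    labels = model.labels.dropna()
    counts = labels.value_counts()
    rows = []
    for cluster, n in counts.items():
        if cluster in annotation.index:
            ctype = annotation.loc[cluster, "type"]
        else:
            ctype = str(cluster)
        rows.append({"cluster": cluster, "type": ctype,
                     "family": family_of(ctype), "n_cells": int(n)})
    table = pd.DataFrame(rows)
    table = table.groupby(["type", "family"], as_index=False)["n_cells"].sum()
    total = table["n_cells"].sum()
    table["pct_of_total"] = 100.0 * table["n_cells"] / total
    fam_totals = table.groupby("family")["n_cells"].transform("sum")
    table["pct_of_family"] = 100.0 * table["n_cells"] / fam_totals
    return table.sort_values("n_cells", ascending=False).reset_index(drop=True)
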