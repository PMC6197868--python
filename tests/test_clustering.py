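"""PCA, SNN graph, community detection, consolidation, doublet exclusion and
dendrogram tests — toy geometries with hand-computed expectations plus
recovery checks on the synthetic gland."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.spatial.distance

from pinealsc import (
    ClusterModel,
    ConsolidationRule,
    build_snn,
    cluster_proportions,
    cluster_tree,
    consolidate,
    exclude_doublets,
    find_communities,
    log_transform,
    normalize_per_cell,
    run_pca,
    scale_genes,
    select_hvg,
    simulate,
)
from pinealsc.clustering import PCAModel, SNNGraph
from pinealsc.preprocess import NormalizedMatrix
from pinealsc.simulate import family_of

from conftest import single_type_config, toy_matrix


def scaled_from(values):
    ng, nc = values.shape
    m = NormalizedMatrix(np.asarray(values, dtype=float),
                         pd.Index([f"g{i}" for i in range(ng)]),
                         pd.Index([f"c{j}" for j in range(nc)]), "ln")
    return scale_genes(m, list(m.gene_ids), clip=None)


class TestPCA:
    def test_rank2_data_fully_captured_with_k2(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 40))
        coords = rng.normal(size=(60, 2)) * [5, 2]
        scaled = scaled_from((coords @ basis).T)
        pca = run_pca(scaled, k=2)
        assert pca.variance_explained.sum() > 0.999

    def test_scores_preserve_distances_at_full_rank(self):
        rng = np.random.default_rng(1)
        scaled = scaled_from(rng.normal(size=(8, 30)))
        k = 8
        pca = run_pca(scaled, k=k)
        d_data = scipy.spatial.distance.pdist(scaled.values.T)
        d_scores = scipy.spatial.distance.pdist(pca.cell_scores)
        assert np.allclose(d_data, d_scores, atol=1e-8)

    def test_duplicated_cell_gets_identical_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 20))
        x[:, 5] = x[:, 3]
        pca = run_pca(scaled_from(x), k=3)
        # scaling is cell-independent, so duplicate columns stay duplicates
        assert np.allclose(pca.cell_scores[3], pca.cell_scores[5])

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(3)
        scaled = scaled_from(rng.normal(size=(12, 25)))
        p1 = run_pca(scaled, k=4)
        p2 = run_pca(scaled, k=4)
        assert np.allclose(p1.components, p2.components)
        for j in range(4):
            i = np.abs(p1.components[:, j]).argmax()
            assert p1.components[i, j] > 0

    def test_k_larger_than_rank_rejected(self):
        scaled = scaled_from(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            run_pca(scaled, k=6)


class TestSNN:
    def make_model(self, points):
        points = np.asarray(points, dtype=float)
        return PCAModel(components=np.eye(points.shape[1]),
                        cell_scores=points,
                        variance_explained=np.ones(points.shape[1]),
                        gene_ids=pd.Index([]),
                        cell_ids=pd.Index([f"c{i}" for i in range(len(points))]))

    def test_identical_neighbor_sets_give_weight_one(self):
        # two tight pairs far apart; k=2 makes each pair share its set
        pts = [[0, 0], [0, 0.01], [100, 0], [100, 0.01]]
        g = build_snn(self.make_model(pts), knn_k=2, prune=0.0)
        w = g.weights.toarray()
        assert w[0, 1] == pytest.approx(1.0)
        assert w[2, 3] == pytest.approx(1.0)

    def test_disjoint_neighborhoods_have_no_edge(self):
        pts = [[0, 0], [0.01, 0], [100, 0], [100.01, 0]]
        g = build_snn(self.make_model(pts), knn_k=2, prune=0.0)
        assert g.weights[0, 2] == 0
        assert g.weights[1, 3] == 0

    def test_six_point_toy_matches_manual_jaccard(self):
        # 1D points: two triplets; with k=3 each cell's neighborhood is its
        # own triplet, so within-triplet Jaccard = 1, across = 0.
        pts = [[0], [1], [2], [50], [51], [52]]
        g = build_snn(self.make_model(pts), knn_k=3, prune=0.0)
        w = g.weights.toarray()
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                if i != j:
                    assert w[i, j] == pytest.approx(1.0)
        assert np.all(w[:3, 3:] == 0)

    def test_graph_is_symmetric_without_self_loops(self):
        rng = np.random.default_rng(4)
        g = build_snn(self.make_model(rng.normal(size=(40, 3))), knn_k=5)
        assert (abs(g.weights - g.weights.T)).nnz == 0
        assert g.weights.diagonal().sum() == 0


class TestCommunities:
    def clique_pair_graph(self):
        n = 10
        w = np.zeros((2 * n, 2 * n))
        w[:n, :n] = 1.0
        w[n:, n:] = 1.0
        np.fill_diagonal(w, 0)
        w[0, n] = w[n, 0] = 0.05
        ids = pd.Index([f"c{i}" for i in range(2 * n)])
        return SNNGraph(sp.csr_matrix(w), ids, knn_k=0, prune=0.0)

    def test_two_cliques_split_into_two_communities(self):
        labels = find_communities(self.clique_pair_graph(), 0.8, seed=0)
        assert labels.nunique() == 2
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1

    def test_resolution_to_zero_gives_one_community(self):
        labels = find_communities(self.clique_pair_graph(), 1e-4, seed=0)
        assert labels.nunique() == 1

    def test_deterministic_for_fixed_seed(self):
        g = self.clique_pair_graph()
        a = find_communities(g, 0.8, seed=3)
        b = find_communities(g, 0.8, seed=3)
        assert a.equals(b)

    def test_invariant_to_cell_order_permutation(self):
        from pinealsc import log_transform, normalize_per_cell, simulate
        from conftest import single_type_config
        from pinealsc.simulate import default_pineal_config

        cfg = default_pineal_config(2000, 13)
        matrix, _ = simulate(cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_cells)

        def labels_for(m):
            ln = log_transform(normalize_per_cell(m))
            hvg = select_hvg(ln)
            scaled = scale_genes(ln, hvg.genes)
            pca = run_pca(scaled, k=10)
            snn = build_snn(pca)
            return find_communities(snn, 0.8, seed=1)

        a = labels_for(matrix).sort_index()
        b = labels_for(matrix.subset_cells(perm)).sort_index()
        assert a.equals(b)


class TestConsolidate:
    def overcluster(self, matrix, resolution=3.0, seed=0):
        norm = normalize_per_cell(matrix)
        ln = log_transform(norm)
        scaled = scale_genes(ln, list(ln.gene_ids))
        pca = run_pca(scaled, k=5)
        snn = build_snn(pca, knn_k=15)
        return norm, find_communities(snn, resolution, seed=seed)

    def test_single_population_is_remerged(self):
        cfg = single_type_config(n_cells=600, n_genes=80, seed=9)
        matrix, _ = simulate(cfg)
        norm, raw = self.overcluster(matrix)
        assert raw.nunique() > 1  # high resolution over-splits
        model = consolidate(norm, raw)
        assert model.labels.nunique() == 1

    def test_alpha_beta_pinealocytes_not_merged(self, pipeline_runs):
        truth, results = pipeline_runs[1]
        res = results["day"]
        types = res.cell_types
        assert {"alpha-pinealocyte", "beta-pinealocyte"} <= set(types.dropna())

    def test_consolidation_map_is_total_and_surjective(self, pipeline_runs):
        _, results = pipeline_runs[1]
        model = results["day"].model
        raw = set(model.raw_labels.dropna())
        assert set(model.consolidation_map) == raw
        assert set(model.consolidation_map.values()) == set(
            model.labels.dropna())

    def test_cyclic_manual_map_rejected(self):
        cfg = single_type_config(n_cells=200, n_genes=40, seed=2)
        matrix, _ = simulate(cfg)
        norm, raw = self.overcluster(matrix)
        rule = ConsolidationRule(manual_merges={0: 1, 1: 0})
        with pytest.raises(ValueError, match="cyclic"):
            consolidate(norm, raw, rule)


class TestExcludeDoublets:
    def test_level_infinity_is_identity(self, pipeline_runs):
        _, results = pipeline_runs[1]
        res = results["day"]
        model = ClusterModel(raw_labels=res.model.raw_labels,
                             consolidation_map=res.model.consolidation_map,
                             labels=res.model.labels)
        out = exclude_doublets(res.norm, model, level=np.inf)
        assert len(out.excluded) == 0

    def test_heterotypic_doublets_flagged(self, pipeline_runs):
        caught = total = 0
        for seed, (truth, results) in pipeline_runs.items():
            for res in results.values():
                tc = truth.cells.reindex(res.matrix.cell_ids)
                hetero = tc["is_doublet"] & (
                    tc["type_a"].map(family_of) != tc["type_b"].map(family_of))
                total += int(hetero.sum())
                caught += int((hetero & tc.index.isin(
                    res.model.excluded.index)).sum())
        assert total > 0
        assert caught / total >= 0.7

    def test_singlets_rarely_flagged(self, pipeline_runs):
        false = labeled = 0
        for seed, (truth, results) in pipeline_runs.items():
            for res in results.values():
                tc = truth.cells.reindex(res.matrix.cell_ids)
                singlet = ~tc["is_doublet"]
                labeled += int(singlet.sum())
                false += int((singlet & tc.index.isin(
                    res.model.excluded.index)).sum())
        assert false / labeled < 0.01


class TestClusterTree:
    def make_norm(self, profiles, n_per=5):
        """Cells drawn exactly at the given per-cluster mean profiles."""
        cols, labels = [], []
        for i, p in enumerate(profiles):
            for j in range(n_per):
                cols.append(p)
                labels.append(i)
        values = np.array(cols, dtype=float).T
        ids = pd.Index([f"c{i}" for i in range(values.shape[1])])
        norm = NormalizedMatrix(values,
                                pd.Index([f"g{i}" for i in range(values.shape[0])]),
                                ids, "per10k")
        model = ClusterModel(raw_labels=pd.Series(labels, index=ids),
                             consolidation_map={i: i for i in range(len(profiles))},
                             labels=pd.Series(labels, index=ids))
        return norm, model

    def full_hvg(self, norm):
        ln = log_transform(
            NormalizedMatrix(norm.values.copy(), norm.gene_ids, norm.cell_ids,
                             "per10k"))
        sel = select_hvg(ln)
        sel.table["selected"] = True
        return sel

    def test_identical_clusters_join_at_zero_height(self):
        norm, model = self.make_norm([[10, 5, 1], [10, 5, 1], [50, 1, 9]])
        model = cluster_tree(norm, model, self.full_hvg(norm))
        heights = model.dendrogram[:, 2]
        assert heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_cluster_tree_matches_manual_distances(self):
        profiles = [[10, 0, 0], [12, 0, 0], [0, 40, 3]]
        norm, model = self.make_norm(profiles)
        model = cluster_tree(norm, model, self.full_hvg(norm))
        logp = np.log1p(np.array(profiles, dtype=float))
        d01 = np.linalg.norm(logp[0] - logp[1])
        # clusters 0 and 1 are nearest -> first merge at distance d01
        assert model.dendrogram[0, 2] == pytest.approx(d01)
        assert set(model.dendrogram[0, :2].astype(int)) == {0, 1}

    def test_pinealocyte_subtypes_are_nearest_leaves(self, pipeline_runs):
        _, results = pipeline_runs[1]
        res = results["day"]
        ann = res.annotation
        labels = res.model.labels
        genes = res.hvg.genes
        sub = np.log1p(res.norm.subset_genes(
            [g for g in genes if g in res.norm.gene_ids]).values)
        clusters = res.model.final_clusters()
        profiles = np.vstack([sub[:, (labels == c).to_numpy()].mean(axis=1)
                              for c in clusters])
        d = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(profiles))
        np.fill_diagonal(d, np.inf)
        types = {c: ann.loc[c, "type"] for c in clusters}
        alpha = next(c for c in clusters if types[c] == "alpha-pinealocyte")
        beta = next(c for c in clusters if types[c] == "beta-pinealocyte")
        i, j = clusters.index(alpha), clusters.index(beta)
        assert d[i].argmin() == j

    def test_single_cluster_rejected(self):
        norm, model = self.make_norm([[1, 2, 3]])
        with pytest.raises(ValueError):
            cluster_tree(norm, model, self.full_hvg(norm))


class TestClusterProportions:
    def make_model(self, sizes):
        labels = []
        for c, n in enumerate(sizes):
            labels += [c] * n
        ids = pd.Index([f"c{i}" for i in range(len(labels))])
        return ClusterModel(raw_labels=pd.Series(labels, index=ids),
                            consolidation_map={c: c for c in range(len(sizes))},
                            labels=pd.Series(labels, index=ids))

    def test_printed_alpha_share_of_pinealocytes(self):
        model = self.make_model([275, 4822])
        ann = pd.DataFrame(
            {"family": ["pinealocyte", "pinealocyte"],
             "type": ["alpha-pinealocyte", "beta-pinealocyte"]},
            index=[0, 1])
        table = cluster_proportions(model, ann).set_index("type")
        share = table.loc["alpha-pinealocyte", "pct_of_family"]
        assert round(share) == 5

    def test_single_cluster_is_100_percent(self):
        model = self.make_model([17])
        ann = pd.DataFrame({"family": ["VLMC"], "type": ["VLMC"]}, index=[0])
        table = cluster_proportions(model, ann)
        assert table["pct_of_total"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        model = self.make_model([10, 20, 30])
        ann = pd.DataFrame(
            {"family": ["astrocyte", "astrocyte", "VLMC"],
             "type": ["alpha-astrocyte", "beta-astrocyte", "VLMC"]},
            index=[0, 1, 2])
        table = cluster_proportions(model, ann)
        assert table["pct_of_total"].sum() == pytest.approx(100.0)
        fam = table[table["family"] == "astrocyte"]
        assert fam["pct_of_family"].sum() == pytest.approx(100.0)
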