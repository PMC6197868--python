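"""Differential-expression core: the pseudocounted fold change, Cohen's d,
BH adjustment against a brute-force oracle, the composite decision rule, the
ambient-gene exclusion and overlap counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pinealsc import (
    DECriteria,
    GeneGroup,
    GroupStats,
    ambient_exclusion,
    bh_adjust,
    cohens_d,
    de_overlap,
    de_test,
    fold_change,
    group_comparison,
    normalize_per_cell,
    reported_fold,
)
from pinealsc.diffexp import composite_de_table
from pinealsc.preprocess import NormalizedMatrix

from conftest import toy_matrix


class TestFoldChange:
    def test_equal_means_give_one(self):
        assert fold_change(3.7, 3.7) == pytest.approx(1.0)

    def test_zero_zero_gives_one(self):
        assert fold_change(0.0, 0.0) == pytest.approx(1.0)

    def test_pseudocount_arithmetic(self):
        assert fold_change(0.99, 0.49) == pytest.approx(2.0)

    def test_product_with_inverse_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 10, 2)
            assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-0.1, 1.0)

    def test_reported_fold_is_direction_free(self):
        assert reported_fold(0.25) == pytest.approx(4.0)
        assert reported_fold(4.0) == pytest.approx(4.0)


class TestCohensD:
    def stats(self, x):
        return GroupStats.from_values(np.asarray(x, dtype=float))

    def test_equal_means_give_zero(self):
        assert cohens_d(self.stats([1, 2, 3]), self.stats([3, 2, 1])) == 0.0

    def test_hand_computed_example(self):
        # means 1 and 2, each s^2 = 2 (n-1 denominator), pooled s = sqrt(2)
        d = cohens_d(self.stats([0, 2]), self.stats([1, 3]))
        assert d == pytest.approx(-1 / np.sqrt(2))

    def test_location_shift_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 2, 500)
        b = a + 3.0
        d = cohens_d(self.stats(a), self.stats(b))
        assert d == pytest.approx(-3.0 / a.std(ddof=1), rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(1, 2, size=7)
        assert cohens_d(self.stats(x), self.stats(y)) == pytest.approx(
            -cohens_d(self.stats(y), self.stats(x)))

    def test_degenerate_zero_spread(self):
        same = GroupStats(mean=2.0, sd=0.0, n=5)
        other = GroupStats(mean=5.0, sd=0.0, n=5)
        assert cohens_d(same, same) == 0.0
        assert cohens_d(other, same) == np.inf

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(GroupStats(1, 0, 1), GroupStats(2, 0, 1))


class TestBHAdjust:
    @staticmethod
    def brute_force(p):
        # step-up definition: adj_(i) = min_{j >= i} p_(j) * m / j, capped
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        sorted_p = p[order]
        adj = np.empty(m)
        for i in range(m):
            adj[i] = min(sorted_p[j] * m / (j + 1) for j in range(i, m))
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_brute_force_on_all_permutations_of_five(self):
        base = [0.001, 0.011, 0.11, 0.24, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_adjust(list(perm)),
                                       self.brute_force(perm), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def make_norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values, pd.Index(genes),
                            pd.Index([f"c{j}" for j in range(values.shape[1])]),
                            "per10k")


class TestCompositeRule:
    def test_inclusive_thresholds_at_exact_boundaries(self):
        # FC of exactly 2.0 and |d| of exactly 0.35 satisfy their criteria
        crit = DECriteria()
        fc = fold_change(0.99, 0.49)   # (0.01+0.99)/(0.01+0.49) = 1.0/0.5
        assert fc == 2.0
        assert fc >= crit.fc_threshold
        d = cohens_d(GroupStats(mean=0.35, sd=1.0, n=200),
                     GroupStats(mean=0.0, sd=1.0, n=200))
        assert d == 0.35
        assert abs(d) >= crit.d_threshold

    def test_fc_below_threshold_is_not_de(self):
        n = 400
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, n)
        xb = 1.0 + noise
        xa = noise - noise.mean() + (1.9 * (0.01 + xb.mean()) - 0.01)
        table = composite_de_table(xa[None, :], xb[None, :], pd.Index(["g"]))
        row = table.iloc[0]
        assert row["fold_change"] == pytest.approx(1.9)
        assert bool(row["pass_p"]) and bool(row["pass_effect"])
        assert not bool(row["pass_fold"])
        assert not bool(row["de"])

    def test_null_simulation_has_almost_no_calls(self):
        rng = np.random.default_rng(2)
        rates = rng.gamma(2.0, 2.0, size=1000)
        xa = rng.poisson(rates[:, None], (1000, 250)).astype(float)
        xb = rng.poisson(rates[:, None], (1000, 250)).astype(float)
        table = composite_de_table(xa, xb, pd.Index([f"g{i}" for i in range(1000)]))
        assert int(table["de"].sum()) <= 2


class TestDETest:
    def planted_dataset(self, n_per_group=200, fold=4.0, seed=0):
        rng = np.random.default_rng(seed)
        n_genes = 300
        rates = rng.gamma(1.5, 2.0, n_genes)
        de_idx = np.arange(20)
        day = rng.poisson(rates[:, None], (n_genes, n_per_group))
        night_rates = rates.copy()
        night_rates[de_idx] *= fold
        night = rng.poisson(night_rates[:, None], (n_genes, n_per_group))
        counts = np.hstack([day, night]) + 0
        counts[-1] += 1  # avoid zero-total cells
        m = toy_matrix(counts)
        norm = normalize_per_cell(m)
        ann = pd.Series("pinealocyte", index=m.cell_ids)
        cond = pd.Series(["day"] * n_per_group + ["night"] * n_per_group,
                         index=m.cell_ids)
        return norm, ann, cond, [f"g{i}" for i in de_idx], rates

    def test_planted_fold4_night_effect_flagged_up(self):
        norm, ann, cond, de_genes, rates = self.planted_dataset()
        table = de_test(norm, ann, "pinealocyte", cond)
        detected = table.loc[de_genes]
        well_expressed = [g for g, r in zip(de_genes, rates[:20])
                         if 1 - np.exp(-r) >= 0.30]
        hits = detected.loc[well_expressed]
        assert (hits["de"] & (hits["direction"] == "night-up")).mean() >= 0.9

    def test_excluded_genes_absent_from_table(self):
        norm, ann, cond, de_genes, _ = self.planted_dataset()
        table = de_test(norm, ann, "pinealocyte", cond, exclusions=["g0"])
        assert "g0" not in table.index

    def test_small_group_rejected(self):
        norm, ann, cond, _, _ = self.planted_dataset(n_per_group=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            de_test(norm, ann, "pinealocyte", cond)


class TestAmbientExclusion:
    def test_pinealocytes_keep_everything(self):
        out = ambient_exclusion(["alpha-pinealocyte", "beta-pinealocyte",
                                 "alpha-astrocyte", "VLMC"])
        assert out["alpha-pinealocyte"] == []
        assert out["beta-pinealocyte"] == []
        assert out["alpha-astrocyte"] == ["Aanat"]
        assert out["VLMC"] == ["Aanat"]

    def test_empty_default_disables_exclusion(self):
        out = ambient_exclusion(["alpha-astrocyte"], default=())
        assert out["alpha-astrocyte"] == []


class TestGroupComparison:
    def test_single_gene_group_reduces_to_per_gene(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(5, (4, 60)).astype(float) + 1
        norm = make_norm(values)
        ann = pd.Series(["A"] * 30 + ["B"] * 30, index=norm.cell_ids)
        r = group_comparison(norm, ann, GeneGroup("solo", ("g2",)), "A", "B")
        a = values[2, :30].mean()
        b = values[2, 30:].mean()
        assert r["ratio"] == pytest.approx(fold_change(a, b))

    def test_identical_types_give_null_result(self):
        rng = np.random.default_rng(4)
        values = rng.poisson(10, (5, 200)).astype(float)
        norm = make_norm(values)
        ann = pd.Series(["A", "B"] * 100, index=norm.cell_ids)
        r = group_comparison(norm, ann, GeneGroup("all", ("g0", "g1")), "A", "B")
        assert 0.9 < r["ratio"] < 1.1
        assert r["p"] > 0.05

    def test_all_group_genes_absent_rejected(self):
        norm = make_norm(np.ones((2, 4)))
        ann = pd.Series(["A", "A", "B", "B"], index=norm.cell_ids)
        with pytest.raises(ValueError):
            group_comparison(norm, ann, GeneGroup("x", ("nope",)), "A", "B")


class TestDEOverlap:
    def test_enumerated_pair(self):
        table = de_overlap({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        row = table[(table["set_a"] == "A") & (table["set_b"] == "B")].iloc[0]
        assert row["intersection"] == 1
        assert row["pct_a_in_b"] == pytest.approx(50.0)

    def test_disjoint_sets(self):
        table = de_overlap({"A": {"g1"}, "B": {"g2"}})
        row = table[(table["set_a"] == "A") & (table["set_b"] == "B")].iloc[0]
        assert row["intersection"] == 0
        assert row["pct_a_in_b"] == 0.0

    def test_subset_gives_100_percent(self):
        table = de_overlap({"A": {"g1", "g2"}, "B": {"g1", "g2", "g3"}})
        row = table[(table["set_a"] == "A") & (table["set_b"] == "B")].iloc[0]
        assert row["pct_a_in_b"] == pytest.approx(100.0)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            de_overlap({"A": {"g1"}})
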