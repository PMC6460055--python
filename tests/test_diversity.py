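"""Diversity metrics and permutation tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.stats.ordination import pcoa as skbio_pcoa

from phyllo import (
    ASVTable,
    alpha_diversity,
    bh_adjust,
    bray_curtis,
    faith_pd,
    gen_tree,
    goods_coverage,
    kruskal_wallis,
    pairwise_permanova,
    pcoa,
    permanova,
    rarefy,
    remove_singletons,
    wilcoxon_rank_sum,
)
from phyllo.containers import ValidationError

from conftest import exhaustive_permanova_p


def _table(counts, sites=None):
    counts = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(len(counts))],
        columns=[f"a{j}" for j in range(len(counts[0]))],
    )
    meta = pd.DataFrame(
        {
            "site": sites or ["Rural"] * len(counts),
            "year": [2014] * len(counts),
            "replicate": list(range(1, len(counts) + 1)),
        },
        index=counts.index,
    )
    return ASVTable(counts=counts, metadata=meta)


class TestRarefy:
    def test_full_depth_keeps_sample_as_multiset(self):
        t = _table([[5, 3, 2], [1, 1, 8]])
        out = rarefy(t, depth=10, seed=0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_min_depth_equalises_rowsums_and_bounds_counts(self, default_community):
        table, _, _ = default_community
        out = rarefy(table, "min", seed=1)
        depth = int(table.sample_sums().min())
        assert (out.sample_sums() == depth).all()
        assert (out.counts.to_numpy() <= table.counts.to_numpy()).all()

    def test_seed_contract(self):
        t = _table([[50, 30, 20], [10, 10, 80]])
        a = rarefy(t, depth=40, seed=7).counts
        b = rarefy(t, depth=40, seed=7).counts
        c = rarefy(t, depth=40, seed=8).counts
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_too_deep_names_offending_samples(self):
        t = _table([[5, 3, 2], [1, 1, 1]])
        with pytest.raises(ValidationError, match="s1"):
            rarefy(t, depth=9)


class TestGoodsCoverage:
    def test_hand_computed_example(self):
        assert goods_coverage([1, 2, 3]) == pytest.approx(1 - 1 / 6)

    def test_extremes(self):
        assert goods_coverage([2, 5, 9]) == 1.0
        assert goods_coverage([1] * 7) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            goods_coverage([0, 0])


class TestRemoveSingletons:
    def test_definition_boundary(self):
        # total 1 dropped; count 1 in each of two samples (total 2) retained;
        # an absent (total 0) column is not a singleton and stays
        t = _table([[1, 1, 0, 4], [0, 1, 0, 4]])
        out = remove_singletons(t)
        assert list(out.counts.columns) == ["a1", "a2", "a3"]

    def test_identity_when_no_singletons(self, small_table):
        out = remove_singletons(small_table)
        pd.testing.assert_frame_equal(out.counts, small_table.counts)


class TestAlpha:
    @pytest.mark.parametrize("s", [2, 5, 17, 64])
    def test_uniform_closed_forms(self, s):
        counts = np.full(s, 9)
        assert alpha_diversity(counts, "shannon") == pytest.approx(np.log2(s))
        assert alpha_diversity(counts, "simpson") == pytest.approx(1 - 1 / s)
        assert alpha_diversity(counts, "observed") == s

    def test_hand_computed_two_taxon_sample(self):
        assert alpha_diversity([8, 2], "shannon") == pytest.approx(0.7219280949)
        assert alpha_diversity([8, 2], "simpson") == pytest.approx(0.32)

    def test_zero_count_taxon_changes_nothing(self):
        for metric in ("observed", "shannon", "simpson"):
            assert alpha_diversity([4, 6, 0], metric) == pytest.approx(
                alpha_diversity([4, 6], metric)
            )

    def test_faith_pd_star_tree_counts_observed_tips(self):
        taxa = [f"t{i}" for i in range(10)]
        tree = gen_tree(taxa, mode="star")
        counts = [1] * 6 + [0] * 4
        assert faith_pd(counts, taxa, tree) == pytest.approx(6.0)

    def test_faith_pd_full_set_is_total_branch_length(self):
        taxa = [f"ASV{i:03d}" for i in range(15)]
        tree = gen_tree(taxa, mode="random-coalescent", seed=2)
        total = sum(n.length or 0 for n in tree.traverse(include_self=False))
        assert faith_pd([1] * 15, taxa, tree) == pytest.approx(total)

    def test_faith_pd_matches_skbio_on_random_subsets(self):
        taxa = [f"ASV{i:03d}" for i in range(20)]
        tree = gen_tree(taxa, mode="random-coalescent", seed=3)
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(0, 3, size=20)
            if counts.sum() == 0:
                continue
            expected = skbio_faith_pd(counts, taxa, tree)
            assert faith_pd(counts, taxa, tree) == pytest.approx(expected)

    def test_faith_pd_missing_tip_named(self):
        tree = gen_tree(["a", "b"], mode="star")
        with pytest.raises(ValidationError, match="ghost"):
            faith_pd([1, 1, 1], ["a", "b", "ghost"], tree)


class TestBrayCurtis:
    def test_hand_values(self):
        t = _table([[1, 2, 3], [3, 2, 1], [1, 2, 3]])
        dm = bray_curtis(t)
        assert dm["s0", "s1"] == pytest.approx(4 / 12)
        assert dm["s0", "s2"] == 0.0

    def test_disjoint_supports_are_maximally_distant(self):
        t = _table([[5, 5, 0, 0], [0, 0, 3, 9]])
        assert bray_curtis(t)["s0", "s1"] == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError, match="s1"):
            bray_curtis(_table([[1, 2, 3], [0, 0, 0]]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    def test_metric_properties_on_random_tables(self, rows):
        dm = bray_curtis(_table(rows))
        D = dm.data
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestPcoa:
    def test_two_points(self):
        dm = DistanceMatrix([[0, 2], [2, 0]], ids=["a", "b"])
        res = pcoa(dm)
        coords = res.coordinates.to_numpy().ravel()
        assert sorted(coords.round(10).tolist()) == [-1.0, 1.0]

    def test_round_trip_of_planted_euclidean_configuration(self):
        from scipy.spatial import procrustes
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(9)])
        res = pcoa(dm)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy()[:, :2])
        assert disparity < 1e-8

    def test_eigenvalue_sum_equals_gower_trace(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        X = rng.random((7, 4))
        D = squareform(pdist(X))
        dm = DistanceMatrix(D, ids=[str(i) for i in range(7)])
        res = pcoa(dm)
        n = 7
        J = np.eye(n) - np.ones((n, n)) / n
        gower = -0.5 * J @ (D**2) @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(gower))

    def test_agrees_with_skbio(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        X = rng.random((8, 5))
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(8)])
        mine = pcoa(dm)
        ref = skbio_pcoa(dm)
        k = mine.proportion_explained.size
        assert np.allclose(
            mine.proportion_explained,
            ref.proportion_explained.to_numpy()[:k],
            atol=1e-8,
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises((ValidationError, Exception)):
            pcoa(DistanceMatrix(np.array([[0.0, 1.0], [0.5, 0.0]]), validate=False))


class TestPermanova:
    def _separated_dm(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        return DistanceMatrix(D, ids=list("abcd"))

    def test_perfectly_separated_clusters(self):
        res = permanova(self._separated_dm(), ["g1", "g1", "g2", "g2"],
                        n_permutations=99, seed=0)
        assert np.isinf(res.pseudo_F)
        # identity split (and its relabelling) keeps F at +inf, so p sits at
        # the floor set by the 3 distinct assignments of 2+2 labels
        assert res.p_value <= 0.5

    def test_exact_enumeration_on_separated_clusters(self):
        res = permanova(self._separated_dm(), ["g1", "g1", "g2", "g2"],
                        method="exact")
        assert res.p_value == pytest.approx(2 / 6)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 1, (3, 3)), rng.normal(1.2, 1, (3, 3))])
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        grouping = ["A"] * 3 + ["B"] * 3
        p_exact = exhaustive_permanova_p(dm, grouping)
        res = permanova(dm, grouping, n_permutations=1999, seed=1)
        # binomial Monte-Carlo error at m=1999
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 1999)
        assert abs(res.p_value - p_exact) < mc_err + 1e-3
        res_exact = permanova(dm, grouping, method="exact")
        assert res_exact.p_value == pytest.approx(p_exact)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(13)
        X = rng.random((10, 6))
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(10)])
        grouping = ["a"] * 5 + ["b"] * 5
        mine = permanova(dm, grouping, n_permutations=9, seed=0)
        ref = sk_permanova(dm, grouping=grouping, permutations=9)
        assert mine.pseudo_F == pytest.approx(float(ref["test statistic"]))

    def test_strata_restrict_permutations(self):
        """Blocked shuffles must leave the year split itself untestable."""
        rng = np.random.default_rng(17)
        X = rng.random((8, 4))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(8)])
        year = ["y1"] * 4 + ["y2"] * 4
        res = permanova(dm, year, n_permutations=99, seed=0, strata=year)
        # permuting within strata never changes the year labels, so every
        # permuted F equals the observed one
        assert res.p_value == 1.0

    def test_degenerate_groups_rejected(self):
        dm = self._separated_dm()
        with pytest.raises(ValidationError):
            permanova(dm, ["g1", "g1", "g1", "g2"])
        with pytest.raises(ValidationError):
            permanova(dm, ["g1", "g1", "g1", "g1"])


class TestPairwisePermanova:
    def test_two_groups_bh_identity(self):
        rng = np.random.default_rng(19)
        from scipy.spatial.distance import pdist, squareform

        X = rng.random((8, 3))
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(8)])
        out = pairwise_permanova(dm, ["a"] * 4 + ["b"] * 4, seed=0)
        assert len(out) == 1
        assert out.loc[0, "p_adjusted"] == out.loc[0, "p_value"]

    def test_three_groups_yield_three_bh_adjusted_pairs(self):
        rng = np.random.default_rng(23)
        from scipy.spatial.distance import pdist, squareform

        X = np.vstack([rng.normal(m, 0.3, (4, 3)) for m in (0.0, 1.5, 4.0)])
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(12)])
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = pairwise_permanova(dm, groups, seed=0)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


class TestRankTests:
    def test_kw_identical_groups(self):
        assert kruskal_wallis([[3, 3], [3, 3, 3]]) == (0.0, 1.0)

    def test_kw_matches_scipy_with_ties(self):
        groups = [[1.0, 2, 5, 7, 5], [3.0, 4, 8], [6.0, 9, 10, 11, 5]]
        H, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert H == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_kw_permutation_p_matches_enumeration_on_tiny_instance(self):
        from itertools import combinations

        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        H_obs, _ = kruskal_wallis([x, y])
        pooled = np.array(x + y)
        n_ge = 0
        for idx in combinations(range(6), 3):
            g1 = pooled[list(idx)]
            g2 = pooled[[i for i in range(6) if i not in idx]]
            H, _ = kruskal_wallis([g1, g2])
            n_ge += H >= H_obs - 1e-12
        p_exact = n_ge / 20
        _, p_perm = kruskal_wallis([x, y], n_permutations=4999, seed=0)
        assert abs(p_perm - p_exact) < 0.03

    def test_two_group_kw_monotone_in_rank_separation(self):
        """H grows as the two samples' ranks separate, like the U statistic."""
        datasets = [
            ([1, 3, 5, 7], [2, 4, 6, 8]),
            ([1, 2, 5, 6], [3, 4, 7, 8]),
            ([1, 2, 3, 4], [5, 6, 7, 8]),
        ]
        h_vals, u_gaps = [], []
        for x, y in datasets:
            H, _ = kruskal_wallis([x, y])
            u, _ = wilcoxon_rank_sum(x, y)
            h_vals.append(H)
            u_gaps.append(abs(u - len(x) * len(y) / 2))
        assert h_vals == sorted(h_vals)
        assert u_gaps == sorted(u_gaps)

    def test_wilcoxon_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])[1] == 1.0

    def test_wilcoxon_most_extreme_ordering(self):
        u, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_wilcoxon_exact_matches_scipy(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 9))
            y = rng.normal(size=rng.integers(2, 9))
            u, p = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert p == pytest.approx(ref.pvalue)

    def test_wilcoxon_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        x = rng.random(6) * 10
        y = rng.random(8) * 10
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x / 3), np.exp(y / 3))
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestBHAdjust:
    def test_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_statsmodels_on_random_inputs(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(37)
        p = rng.random(25)
        mine = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_values_bounded_and_order_preserving(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
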