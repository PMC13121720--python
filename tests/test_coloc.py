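"""Trait-network extraction, permutation null, COLOC statistics and oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qnetcoloc.coloc import (
    bh_correct,
    coloc_statistics,
    extract_trait_network,
    permutation_null_sizes,
    prioritized_genes,
    shared_gene_test,
    trait_similarity,
)
from qnetcoloc.nps import CombinedNPS, NPSVector


def _nps(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return NPSVector(score=pd.Series(np.asarray(values, dtype=float), index=genes))


class TestExtractTraitNetwork:
    def test_threshold_examples(self):
        c = _nps([2.0, 1.5, 4.0], ["a", "b", "c"])
        r = _nps([2.0, 1.5, 0.5], ["a", "b", "c"])
        net = extract_trait_network(c, r, tau=1.0, tau_star=3.0)
        # a: product 4 > 3 -> in; b: 2.25 < 3 -> out; c: fails individual tau
        assert net.members == {"a"}

    def test_empty_result_allowed(self):
        net = extract_trait_network(_nps([0.0, -1.0]), _nps([0.0, -1.0]))
        assert net.members == frozenset()

    def test_tau_star_must_dominate_tau(self):
        with pytest.raises(ValueError, match="tau"):
            extract_trait_network(_nps([1.0]), _nps([1.0]), tau=2.0, tau_star=1.0)

    @pytest.mark.parametrize(
        "t1,ts1,t2,ts2", [(0.5, 1.0, 1.0, 3.0), (1.0, 2.0, 1.5, 2.0), (0.0, 0.0, 2.0, 5.0)]
    )
    def test_monotone_in_thresholds(self, t1, ts1, t2, ts2):
        rng = np.random.default_rng(0)
        c = _nps(rng.normal(1, 1.5, 200))
        r = _nps(rng.normal(1, 1.5, 200))
        loose = extract_trait_network(c, r, tau=t1, tau_star=ts1)
        strict = extract_trait_network(c, r, tau=t2, tau_star=ts2)
        assert strict.members <= loose.members


class TestPermutationNull:
    def test_identical_scores_give_constant_null(self):
        c = _nps([1.5] * 30)
        r = _nps(np.linspace(-1, 4, 30))
        obs = extract_trait_network(c, r).size
        sizes = permutation_null_sizes(c, r, shared_genes=set(), n_perm=20, rng_seed=0)
        assert (sizes == obs).all()

    def test_determinism(self):
        rng = np.random.default_rng(1)
        c, r = _nps(rng.normal(size=50)), _nps(rng.normal(size=50))
        a = permutation_null_sizes(c, r, set(), n_perm=30, rng_seed=11)
        b = permutation_null_sizes(c, r, set(), n_perm=30, rng_seed=11)
        assert np.array_equal(a, b)

    def test_stratified_shuffle_preserves_per_stratum_multisets(self):
        # re-implement one permutation step alongside to check the strata
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        c = _nps(rng.normal(size=40), genes)
        r = _nps(rng.normal(size=40), genes)
        shared = set(genes[:7])
        # with tau = -inf-ish thresholds every gene counts, so null sizes must
        # equal the observed size regardless of the shuffle — the multiset of
        # scores entering the criterion per stratum is preserved
        sizes = permutation_null_sizes(
            c, r, shared, tau=-100.0, tau_star=-100.0, n_perm=25, rng_seed=3
        )
        assert (sizes == 40).all()
        # shared-only thresholds: count of shared genes above tau is invariant
        # when the non-shared stratum is fully below tau
        c2_vals = np.concatenate([np.full(7, 2.0), np.full(33, -5.0)])
        r2_vals = np.full(40, 3.0)
        c2, r2 = _nps(c2_vals, genes), _nps(r2_vals, genes)
        sizes2 = permutation_null_sizes(c2, r2, shared, n_perm=25, rng_seed=4)
        assert (sizes2 == 7).all()

    def test_unknown_shared_gene_rejected(self):
        c, r = _nps([1.0, 2.0]), _nps([1.0, 2.0])
        with pytest.raises(ValueError, match="universe"):
            permutation_null_sizes(c, r, {"nope"}, n_perm=5)

    def test_null_sizes_approximately_normal_for_large_traits(self):
        # observed size >= 30: QQ correlation against a fitted normal > 0.95
        rng = np.random.default_rng(5)
        n = 600
        c = _nps(rng.normal(1.2, 1.0, n))
        r = _nps(rng.normal(1.2, 1.0, n))
        obs = extract_trait_network(c, r).size
        assert obs >= 30
        sizes = permutation_null_sizes(c, r, set(), n_perm=400, rng_seed=6)
        (osm, osr), (slope, intercept, qq_r) = stats.probplot(sizes, dist="norm")
        assert qq_r > 0.95


class TestColocStatistics:
    def test_score_is_observed_over_expected(self):
        res = coloc_statistics(200, [100] * 10 + [100] * 10)
        assert res.coloc_score == pytest.approx(2.0)

    def test_observed_at_mean_gives_p_half(self):
        res = coloc_statistics(100, [90, 100, 110])
        assert res.coloc_score == pytest.approx(1.0)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_z_and_upper_tail_p(self):
        # mean 100, sd 10 -> z = 10, p = survival at 10
        null = np.array([90, 110, 90, 110, 90, 110, 90, 110], dtype=float)
        sd = null.std(ddof=1)
        res = coloc_statistics(200, null)
        assert res.z == pytest.approx((200 - 100) / sd)
        assert res.p == pytest.approx(float(stats.norm.sf(res.z)))

    def test_zero_mean_null_warns_nan_score(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = coloc_statistics(5, [0, 0, 0])
        assert np.isnan(res.coloc_score) and res.p == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            coloc_statistics(5, [])


class TestBHCorrect:
    @staticmethod
    def _bh_oracle(p):
        """Brute-force step-up: sort, adjust, enforce monotonicity, cap."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_hand_example(self):
        assert np.allclose(bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_tied_values(self):
        assert bh_correct([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_correct([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.2])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        p=st.lists(
            st.sampled_from([0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.8, 1.0]),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_correct(p), self._bh_oracle(p), atol=1e-12)


class TestSharedGeneTest:
    @staticmethod
    def _enumeration_oracle(background, n_common, n_rare, k):
        """P(|overlap| >= k) by exhaustive enumeration of rare-set choices."""
        universe = range(background)
        common = set(range(n_common))
        total = hits = 0
        for rare in itertools.combinations(universe, n_rare):
            total += 1
            if len(common & set(rare)) >= k:
                hits += 1
        return hits / total

    def test_zero_overlap_gives_one(self):
        assert shared_gene_test(10, 20, 0, background=1000) == pytest.approx(1.0)

    def test_small_case_exact_fraction(self):
        # background 10, sets of 3 and 3, overlap >= 2 -> 22/120
        assert shared_gene_test(3, 3, 2, background=10) == pytest.approx(22 / 120)

    @pytest.mark.parametrize(
        "bg,nc,nr,k",
        [(10, 3, 3, 2), (12, 4, 3, 1), (12, 5, 4, 3), (8, 4, 4, 4), (9, 2, 6, 2)],
    )
    def test_matches_enumeration_oracle(self, bg, nc, nr, k):
        assert shared_gene_test(nc, nr, k, background=bg) == pytest.approx(
            self._enumeration_oracle(bg, nc, nr, k), abs=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            shared_gene_test(3, 3, 4, background=10)
        with pytest.raises(ValueError):
            shared_gene_test(3, 20, 1, background=10)


class TestPrioritizedGenes:
    def test_intersections_and_disjoint_variants(self):
        tn = extract_trait_network(
            _nps([2.0, 2.0, 2.0, 0.0], list("ABCD")),
            _nps([2.0, 2.0, 2.0, 0.0], list("ABCD")),
        )
        assert tn.members == {"A", "B", "C"}
        pri = prioritized_genes({"A", "B", "D"}, {"B", "C"}, tn)
        assert pri.common == {"A", "B"}
        assert pri.rare == {"B", "C"}
        assert pri.common_disjoint == {"A"}
        assert pri.rare_disjoint == {"C"}

    def test_empty_members(self):
        tn = extract_trait_network(_nps([0.0]), _nps([0.0]))
        pri = prioritized_genes({"g0"}, {"g0"}, tn)
        assert pri.common == frozenset() and pri.rare == frozenset()


class TestTraitSimilarity:
    def test_identical_vectors(self):
        nps = CombinedNPS(score=pd.Series([1.0, 2.0, 3.0], index=list("ABC")))
        assert trait_similarity(nps, {"A", "B"}, nps, {"B", "C"}) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = CombinedNPS(score=pd.Series([1.0, 0.0], index=["A", "B"]))
        b = CombinedNPS(score=pd.Series([0.0, 1.0], index=["A", "B"]))
        assert trait_similarity(a, {"A"}, b, {"B"}) == pytest.approx(0.0)

    def test_hand_cosine(self):
        a = CombinedNPS(score=pd.Series([1.0, 0.0], index=["A", "B"]))
        b = CombinedNPS(score=pd.Series([1.0, 1.0], index=["A", "B"]))
        assert trait_similarity(a, {"A", "B"}, b, {"A", "B"}) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_empty_union_rejected(self):
        a = CombinedNPS(score=pd.Series([1.0], index=["A"]))
        with pytest.raises(ValueError, match="empty"):
            trait_similarity(a, set(), a, set())
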