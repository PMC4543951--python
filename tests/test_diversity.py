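import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from trophospec import anosim, bray_curtis, hutcheson_t, mann_whitney, shannon

from conftest import make_diet


class TestShannon:
    def test_uniform_two_taxa(self):
        res = shannon([5, 5])
        assert res.H == pytest.approx(math.log(2))
        assert res.J == pytest.approx(1.0)

    def test_single_taxon_zero_diversity(self):
        res = shannon([7])
        assert res.H == 0.0
        assert res.J is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])

    def test_autumn_environment_evenness(self, table1):
        res = shannon(table1.env_counts["autumn"])
        assert round(res.J, 2) == 0.68

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = rng.integers(0, 30, size=rng.integers(2, 8))
            if c.sum() == 0:
                continue
            res = shannon(c)
            assert 0 <= res.H <= math.log(max(res.S, 2)) + 1e-12
            scaled = shannon(c * 7)
            assert scaled.H == pytest.approx(res.H)


class TestHutchesonT:
    def test_identical_vectors_give_t_zero(self):
        t, df, p = hutcheson_t([10, 5, 3], [10, 5, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [10, 5, 3], [4, 4, 12]
        t1, _, p1 = hutcheson_t(a, b)
        t2, _, p2 = hutcheson_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_seasonal_diet_diversity_differs(self, table1):
        # autumn diet is significantly more diverse than spring diet
        t, _, p = hutcheson_t(
            table1.diet_counts["autumn"], table1.diet_counts["spring"]
        )
        assert t > 0
        assert p < 0.001

    def test_seasonal_environment_diversity_differs(self, table1):
        _, _, p = hutcheson_t(
            table1.env_counts["autumn"], table1.env_counts["spring"]
        )
        assert p < 0.001

    def test_two_single_taxon_samples_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hutcheson_t([5], [9])


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([3, 0], [0, 9]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([6, 2], [2, 2]) == pytest.approx(4 / 12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 40), min_size=2, max_size=6),
        st.data(),
    )
    def test_symmetry_and_bounds(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 40), min_size=len(x), max_size=len(x))
        )
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= d <= 1.0


def brute_force_anosim(props, codes):
    """Independent oracle: exhaustive-permutation ANOSIM on raw arrays."""
    n = len(codes)
    ranks = rankdata(pdist(props, metric="braycurtis"))
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(c):
        c = np.asarray(c)
        within = c[iu] == c[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    obs = r_stat(codes)
    all_r = [r_stat(p) for p in set(itertools.permutations(codes))]
    p = sum(r >= obs - 1e-12 for r in all_r) / len(all_r)
    return obs, p


class TestAnosim:
    def test_disjoint_groups_give_r_one(self):
        dm = make_diet([[5, 0], [9, 0], [0, 4], [0, 7]])
        res = anosim(dm, ["a", "a", "b", "b"], exhaustive=True)
        assert res.R == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 8, size=(7, 4)) + 1
        dm = make_diet(counts)
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        res = anosim(dm, groups, exhaustive=True)
        obs, p = brute_force_anosim(dm.proportions(), [0, 0, 0, 1, 1, 1, 1])
        assert res.R == pytest.approx(obs)
        assert res.p == pytest.approx(p)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim, DistanceMatrix

        rng = np.random.default_rng(4)
        counts = rng.integers(0, 9, size=(10, 5)) + 1
        dm = make_diet(counts)
        groups = ["a"] * 5 + ["b"] * 5
        res = anosim(dm, groups, n_perm=99, seed=1)
        sq = np.zeros((10, 10))
        iu, ju = np.triu_indices(10, k=1)
        d = pdist(dm.proportions(), metric="braycurtis")
        sq[iu, ju] = d
        sq += sq.T
        sk = sk_anosim(DistanceMatrix(sq), grouping=groups, permutations=99)
        assert res.R == pytest.approx(sk["test statistic"])

    def test_unstructured_labels_not_significant(self):
        # with labels carrying no structure, R stays near 0 and p is
        # non-significant for most relabelings (each single test has a 5%
        # false-positive rate by construction, so majority-vote over draws)
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 12, size=(24, 5)) + 1
        dm = make_diet(counts)
        results = [
            anosim(dm, rng.permutation(["a"] * 12 + ["b"] * 12),
                   n_perm=499, seed=int(rng.integers(2**31)))
            for _ in range(7)
        ]
        assert np.median([abs(r.R) for r in results]) < 0.15
        assert sum(r.p > 0.05 for r in results) >= 5

    def test_group_of_one_rejected(self):
        dm = make_diet([[1, 0], [0, 1], [1, 1]])
        with pytest.raises(ValueError):
            anosim(dm, ["a", "b", "b"], seed=0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 9, size=(8, 4)) + 1
        dm = make_diet(counts)
        g1 = ["a", "a", "a", "a", "b", "b", "b", "b"]
        g2 = ["x" if g == "b" else "y" for g in g1]
        r1 = anosim(dm, g1, exhaustive=True)
        r2 = anosim(dm, g2, exhaustive=True)
        assert r1.R == pytest.approx(r2.R)
        assert r1.p == pytest.approx(r2.p)


def brute_force_mann_whitney(a, b):
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) arrangements."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_of(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
        return u

    obs = u_of(range(n_a))
    mean_u = n_a * (len(pooled) - n_a) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    extreme = sum(abs(u - mean_u) >= abs(obs - mean_u) - 1e-12 for u in us)
    return obs, extreme / len(us)


class TestMannWhitney:
    def test_identical_samples_centered_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_complete_separation_gives_u_zero(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_exact_p_matches_enumeration(self):
        a = np.array([1.3, 2.7, 0.4])
        b = np.array([2.1, 3.9, 5.5])
        u, p = mann_whitney(a, b)
        obs, p_oracle = brute_force_mann_whitney(a, b)
        assert p == pytest.approx(p_oracle)
        assert u == pytest.approx(min(obs, 9 - obs))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
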