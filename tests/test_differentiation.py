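import numpy as np
import pytest

from ssrdem.differentiation import (
    DistanceMatrix,
    amova,
    global_fst,
    nei_distance,
    nj_tree,
    pairwise_fst,
    pcoa,
    simple_matching_dissimilarity,
)
from ssrdem.io_formats import MISSING, GenotypeMatrix, Partition

from conftest import random_matrix


def two_pop_matrix(calls_a, calls_b, L=1):
    """One-locus two-group matrix from explicit call lists."""
    n = len(calls_a) + len(calls_b)
    arr = np.array([[c] for c in calls_a + calls_b])
    g = GenotypeMatrix(tuple(f"i{i:03d}" for i in range(n)), ("L1",), arr)
    labels = {f"i{i:03d}": ("A" if i < len(calls_a) else "B") for i in range(n)}
    return g, Partition(labels)


def wc_theta_oracle(pops):
    """Independent spreadsheet-style evaluation of Weir-Cockerham theta for
    one locus; ``pops`` is a list of (n, 2) call arrays."""
    r = len(pops)
    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    A = B = C = 0.0
    for a in alleles:
        p_i = np.array([np.mean(pop == a) for pop in pops])
        h_i = np.array([
            np.mean((pop[:, 0] != pop[:, 1]) & ((pop[:, 0] == a) | (pop[:, 1] == a)))
            for pop in pops
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        A += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        B += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        C += hbar / 2
    return A / (A + B + C)


class TestPairwiseFst:
    def test_identical_frequency_groups_near_zero(self):
        rng = np.random.default_rng(4)
        g = random_matrix(rng, n=400, L=10, n_alleles=5)
        p = Partition({ind: ("A" if i < 200 else "B")
                       for i, ind in enumerate(g.individuals)})
        dm, _, theta = pairwise_fst(g, p)
        assert abs(theta) < 0.02

    def test_complete_fixation_gives_one(self, two_fixed_clusters):
        g, p = two_fixed_clusters
        dm, _, theta = pairwise_fst(g, p)
        assert theta == pytest.approx(1.0)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        # pop1 ~ (0.5, 0.5) with 13 AA / 24 AB / 13 BB; pop2 fixed for A
        calls_a = [(1, 1)] * 13 + [(1, 2)] * 24 + [(2, 2)] * 13
        calls_b = [(1, 1)] * 50
        g, p = two_pop_matrix(calls_a, calls_b)
        _, _, theta = pairwise_fst(g, p)
        oracle = wc_theta_oracle([np.array(calls_a), np.array(calls_b)])
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_pairwise_equals_global_for_two_groups(self):
        rng = np.random.default_rng(10)
        g = random_matrix(rng, n=60, L=6, n_alleles=4)
        p = Partition({ind: ("A" if i < 30 else "B")
                       for i, ind in enumerate(g.individuals)})
        dm, _, theta = pairwise_fst(g, p)
        assert dm.values[0, 1] == pytest.approx(theta)
        assert theta == pytest.approx(global_fst(g, p))

    def test_permutation_p_small_for_fixed_difference(self, two_fixed_clusters):
        g, p = two_fixed_clusters
        _, pvals, _ = pairwise_fst(g, p, n_perm=99, seed=1)
        assert pvals.iloc[0, 1] <= 0.01 + 1e-9

    def test_permutation_null_uniformity(self):
        # p-values under no differentiation: close to uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(17)
        pvals = []
        for i in range(200):
            g = random_matrix(rng, n=20, L=3, n_alleles=3)
            p = Partition({ind: ("A" if j < 10 else "B")
                           for j, ind in enumerate(g.individuals)})
            _, pm, _ = pairwise_fst(g, p, n_perm=49,
                                    seed=int(rng.integers(2**31 - 1)))
            pvals.append(pm.iloc[0, 1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        calls = [(1, 2)] * 10
        g, p = two_pop_matrix(calls, calls)
        dm = nei_distance(g, p)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation_single_locus(self):
        # p1 = (0.75, 0.25), p2 = (0.25, 0.75): D = -ln 0.6 = 0.5108
        calls_a = [(1, 1)] * 3 + [(2, 2)]
        calls_b = [(1, 1)] + [(2, 2)] * 3
        g, p = two_pop_matrix(calls_a, calls_b)
        dm = nei_distance(g, p, variant="standard_1972")
        assert dm.values[0, 1] == pytest.approx(-np.log(0.6), abs=1e-12)

    def test_disjoint_allele_sets_infinite(self, two_fixed_clusters):
        g, p = two_fixed_clusters
        with pytest.warns(UserWarning, match="no alleles"):
            dm = nei_distance(g, p)
        assert np.isinf(dm.values[0, 1])

    def test_unbiased_variant_differs_and_shrinks(self):
        rng = np.random.default_rng(3)
        g = random_matrix(rng, n=20, L=5, n_alleles=4)
        p = Partition({ind: ("A" if i < 10 else "B")
                       for i, ind in enumerate(g.individuals)})
        d72 = nei_distance(g, p, "standard_1972").values[0, 1]
        d78 = nei_distance(g, p, "unbiased_1978").values[0, 1]
        assert d72 != d78
        assert d78 < d72  # removing within-pop bias lowers D


class TestAmova:
    def test_random_split_of_panmictic_sample(self):
        rng = np.random.default_rng(12)
        g = random_matrix(rng, n=200, L=10, n_alleles=5)
        p = Partition({ind: f"g{i % 4}" for i, ind in enumerate(g.individuals)})
        res = amova(g, p, n_perm=99, seed=0)
        assert res.table.loc["among_groups", "pct"] < 3
        assert res.p_value > 0.05

    def test_fixed_difference_all_variance_between(self, two_fixed_clusters):
        g, p = two_fixed_clusters
        res = amova(g, p)
        assert res.table.loc["among_groups", "pct"] == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_percentages_sum_and_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        g = random_matrix(rng, n=40, L=4, n_alleles=3)
        p = Partition({ind: ("A" if i < 20 else "B")
                       for i, ind in enumerate(g.individuals)})
        res = amova(g, p)
        assert res.table["pct"].iloc[:2].sum() == pytest.approx(100.0, abs=0.1)
        # relabel alleles with an arbitrary injective map
        relabeled = np.where(g.calls == MISSING, MISSING, g.calls * 7 + 3)
        g2 = GenotypeMatrix(g.individuals, g.loci, relabeled)
        res2 = amova(g2, p)
        assert res2.phi_st == pytest.approx(res.phi_st, abs=1e-12)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        g = random_matrix(rng, n=10, L=2)
        p = Partition({ind: "only" for ind in g.individuals})
        with pytest.raises(ValueError):
            amova(g, p)


class TestSimpleMatching:
    def test_identical_and_disjoint(self):
        calls = np.array([
            [[1, 2], [3, 3]],
            [[1, 2], [3, 3]],
            [[8, 9], [7, 7]],
        ])
        g = GenotypeMatrix(("a", "b", "c"), ("l1", "l2"), calls)
        d = simple_matching_dissimilarity(g).values
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)

    def test_half_shared_call(self):
        calls = np.array([[[1, 2]], [[1, 3]]])
        g = GenotypeMatrix(("a", "b"), ("l1",), calls)
        assert simple_matching_dissimilarity(g).values[0, 1] == pytest.approx(0.5)

    def test_homozygote_vs_heterozygote_shares_one(self):
        calls = np.array([[[1, 1]], [[1, 2]]])
        g = GenotypeMatrix(("a", "b"), ("l1",), calls)
        assert simple_matching_dissimilarity(g).values[0, 1] == pytest.approx(0.5)

    def test_missing_loci_excluded_pairwise(self):
        calls = np.array([
            [[1, 2], [MISSING, MISSING]],
            [[1, 2], [5, 5]],
        ])
        g = GenotypeMatrix(("a", "b"), ("l1", "l2"), calls)
        assert simple_matching_dissimilarity(g).values[0, 1] == pytest.approx(0.0)


class TestNjTree:
    def test_three_leaf_closed_form(self):
        d = DistanceMatrix(("a", "b", "c"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        res = nj_tree(d)
        tree = res.tree
        # three-point formulas: a = (d_ab + d_ac - d_bc)/2, etc.
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["a"] == pytest.approx(1.0)
        assert lens["b"] == pytest.approx(2.0)
        assert lens["c"] == pytest.approx(3.0)

    def test_additive_four_leaf_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive matrix, NJ must invert it
        dist = {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }
        labels = ("a", "b", "c", "d")
        m = np.zeros((4, 4))
        for (x, y), v in dist.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        res = nj_tree(DistanceMatrix(labels, m))
        tree = res.tree
        # a and b must be sisters: their smallest containing clade is {a,b}
        lca = tree.lca([tree.find("a"), tree.find("b")])
        assert {t.name for t in lca.tips()} in ({"a", "b"}, {"c", "d"})
        # path lengths reproduce the input exactly (additivity)
        for (x, y), v in dist.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(v)

    def test_bootstrap_full_support_for_clean_split(self):
        # two clusters sharing one allele (finite Nei distance), split into
        # four entities; the A|B bipartition survives every locus resample
        n, L = 40, 8
        calls = np.empty((n, L, 2), dtype=np.int64)
        calls[: n // 2] = (11, 11)
        calls[n // 2:] = (11, 22)
        g = GenotypeMatrix(tuple(f"i{i:02d}" for i in range(n)),
                           tuple(f"l{l}" for l in range(L)), calls)
        labels = {ind: ("A" if i < n // 2 else "B") + str(i % 2)
                  for i, ind in enumerate(g.individuals)}
        p4 = Partition(labels)
        d = nei_distance(g, p4, "standard_1972")
        # identical-composition subgroups sit at distance 0; nudge off-diagonal
        vals = d.values + 1e-9 * (1 - np.eye(4))
        d = DistanceMatrix(d.labels, vals, "nei")
        res = nj_tree(d, bootstrap=dict(
            distance_fn=lambda gb: nei_distance(gb, p4, "standard_1972"),
            genotypes=g, replicates=50, seed=3))
        assert res.supports
        assert all(v == 100.0 for v in res.supports.values())

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(DistanceMatrix(("a", "b", "c"), m))


class TestPcoa:
    def test_recovers_line_coordinates(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(("a", "b", "c", "d"), d), n_axes=3)
        ax1 = res.coordinates["axis1"].to_numpy()
        rec = np.abs(ax1[:, None] - ax1[None, :])
        assert np.allclose(rec, d, atol=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planar_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(tuple("abcdef"), d), n_axes=2)
        c = res.coordinates.to_numpy()
        rec = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        assert np.allclose(rec, d, atol=1e-9)

    def test_separates_fixed_clusters(self, two_fixed_clusters):
        g, p = two_fixed_clusters
        d = simple_matching_dissimilarity(g)
        res = pcoa(d, n_axes=1)
        ax1 = res.coordinates["axis1"].to_numpy()
        side_a, side_b = ax1[:30], ax1[30:]
        assert max(side_a) < min(side_b) or min(side_a) > max(side_b)

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(("a", "b"), m))
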