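import itertools

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from phylosym import (HostTree, congruence_test, mantel, mc_distance,
                      rf_distance, simulate_tree, subsampled_mantel, upgma)
from phylosym.congruence import cophenetic_matrix


def random_dm(n, rng, ids=None):
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


def rooted_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def oracle_clusters(tree):
    """Independent cluster enumeration: a leaf subset is a cluster iff the
    leaf set of its MRCA equals the subset (checked for every subset)."""
    tree.is_rooted = True
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for r in range(2, len(leaves)):
        for combo in itertools.combinations(leaves, r):
            taxa = [tree.taxon_namespace.get_taxon(x) for x in combo]
            mrca = tree.mrca(taxa=taxa)
            below = frozenset(l.taxon.label for l in mrca.leaf_iter())
            if below == frozenset(combo):
                out.add(below)
    return out


def oracle_mc(c1, c2):
    """Exhaustive minimum-weight matching over all permutations."""
    a, b = list(c1), list(c2)
    m = max(len(a), len(b))
    a += [frozenset()] * (m - len(a))
    b += [frozenset()] * (m - len(b))
    best = None
    for perm in itertools.permutations(range(m)):
        w = sum(len(a[i] ^ b[perm[i]]) for i in range(m))
        best = w if best is None else min(best, w)
    return best or 0


class TestMantel:
    def test_identical_matrices_r_one(self):
        d = random_dm(6, np.random.default_rng(0))
        r, p = mantel(d, d, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_anti_ordered_r_minus_one(self):
        d = random_dm(5, np.random.default_rng(1))
        flipped = d.data.max() - d.data
        np.fill_diagonal(flipped, 0)
        b = DistanceMatrix(flipped, ids=list(d.ids))
        r, _ = mantel(d, b, n_permutations=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_matches_skbio(self):
        rng = np.random.default_rng(2)
        a, b = random_dm(8, rng), random_dm(8, rng)
        r, _ = mantel(a, b, n_permutations=0)
        r_ref, _, _ = skbio_mantel(a, b, permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_id_mismatch_errors(self):
        rng = np.random.default_rng(3)
        a = random_dm(5, rng)
        b = random_dm(5, rng, ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="different id sets"):
            mantel(a, b)

    def test_zero_variance_flagged(self):
        a = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        b = random_dm(4, np.random.default_rng(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="undefined"):
            mantel(a, b, n_permutations=0)

    def test_type_one_error_calibrated(self):
        """Independent random matrices: rejection at 0.05 near 0.05."""
        rng = np.random.default_rng(5)
        n_sims, rej = 300, 0
        for s in range(n_sims):
            a, b = random_dm(8, rng), random_dm(8, rng)
            _, p = mantel(a, b, n_permutations=99, seed=s)
            rej += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rej / n_sims - 0.05) <= 3 * se


class TestSubsampledMantel:
    def test_full_size_single_draw_reproduces_mantel(self):
        rng = np.random.default_rng(6)
        a, b = random_dm(7, rng), random_dm(7, rng, ids=None)
        batch = subsampled_mantel(a, b, subsample_size=7, n_resamplings=3,
                                  n_permutations=99, seed=0)
        assert np.unique(batch.r_values).size == 1
        r, _ = mantel(a, b, n_permutations=0)
        assert batch.r_values[0] == pytest.approx(r)

    def test_perfect_phylosymbiosis_mean_r_one(self):
        tree = simulate_tree(10, seed=1)
        from phylosym import patristic_distances
        hd = patristic_distances(tree, sorted(tree.tip_labels))
        batch = subsampled_mantel(hd, hd, subsample_size=6, n_resamplings=10,
                                  n_permutations=99, seed=0)
        assert batch.mean_r == pytest.approx(1.0)

    def test_oversized_subsample_errors(self):
        rng = np.random.default_rng(7)
        a = random_dm(5, rng)
        with pytest.raises(ValueError, match="exceeds available"):
            subsampled_mantel(a, a, subsample_size=9, n_resamplings=2)


class TestUpgma:
    def test_hand_executed_merge_order(self):
        d = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                           ids=["A", "B", "C"])
        tree = upgma(d)
        coph = cophenetic_matrix(tree)
        assert coph["A", "B"] == pytest.approx(2.0)  # merged at height 1
        assert coph["A", "C"] == pytest.approx(4.0)  # C joins at height 2
        assert coph["B", "C"] == pytest.approx(4.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        d = random_dm(6, rng)
        perm = rng.permutation(6)
        d2 = DistanceMatrix(d.data[np.ix_(perm, perm)],
                            ids=[d.ids[i] for i in perm])
        c1, c2 = cophenetic_matrix(upgma(d)), cophenetic_matrix(upgma(d2))
        np.testing.assert_allclose(c1.data, c2.filter(c1.ids).data, atol=1e-12)

    def test_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(9)
        d = random_dm(7, rng)
        c = cophenetic_matrix(upgma(d))
        for i, j, k in itertools.combinations(range(7), 3):
            trio = sorted([c.data[i, j], c.data[i, k], c.data[j, k]])
            assert trio[2] - trio[1] < 1e-9

    def test_matches_scipy_average_linkage(self):
        """Cross-check cophenetic distances against scipy's UPGMA."""
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(10)
        d = random_dm(8, rng)
        mine = cophenetic_matrix(upgma(d))
        ref = squareform(cophenet(average(squareform(d.data))))
        np.testing.assert_allclose(mine.filter(d.ids).data, ref, atol=1e-9)


class TestTreeDistances:
    def test_identical_trees_zero(self):
        t = rooted_tree("((a,b),(c,d));")
        t2 = rooted_tree("((a,b),(c,d));")
        assert rf_distance(t, t2) == 0
        assert mc_distance(t, t2) == 0

    def test_four_leaf_swap_rf_four(self):
        t1 = rooted_tree("((a,b),(c,d));")
        t2 = rooted_tree("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 4  # {ab},{cd} vs {ac},{bd}

    def test_leaf_set_mismatch_errors(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(rooted_tree("((a,b),(c,d));"), rooted_tree("((a,b),(c,e));"))

    def test_caterpillar_vs_balanced_mc_matches_exhaustive(self):
        t1 = rooted_tree("(((((a,b),c),d),e),f);")
        t2 = rooted_tree("(((a,b),c),((d,e),f));")
        from phylosym.trees import tree_clusters
        expected = oracle_mc(tree_clusters(t1), tree_clusters(t2))
        assert mc_distance(t1, t2) == expected

    def test_random_pairs_match_brute_force_oracles(self):
        """RF against subset-MRCA cluster enumeration, MC against exhaustive
        matching, on random 8-leaf tree pairs."""
        for seed in range(4):
            ta = simulate_tree(8, seed=100 + seed).tree
            tb = simulate_tree(8, seed=200 + seed).tree
            ca, cb = oracle_clusters(ta), oracle_clusters(tb)
            assert rf_distance(ta, tb) == len(ca ^ cb)
            assert mc_distance(ta, tb) == oracle_mc(ca, cb)

    def test_consistent_relabeling_invariance(self):
        t1 = simulate_tree(8, seed=300).tree
        t2 = simulate_tree(8, seed=301).tree
        rf0, mc0 = rf_distance(t1, t2), mc_distance(t1, t2)
        labels = sorted(l.taxon.label for l in t1.leaf_node_iter())
        rng = np.random.default_rng(0)
        new = {a: b for a, b in zip(labels, rng.permutation(labels))}
        for t in (t1, t2):
            for leaf in t.leaf_node_iter():
                leaf.taxon.label = new[leaf.taxon.label]
        assert rf_distance(t1, t2) == rf0
        assert mc_distance(t1, t2) == mc0


class TestCongruenceTest:
    def test_identical_topology_fully_congruent(self):
        host = simulate_tree(8, seed=4)
        res = congruence_test(host, host.tree, n_permutations=199, seed=0)
        assert res.nrf == 0.0 and res.nmc == 0.0
        assert res.p_rf == pytest.approx(1 / 200)
        assert res.p_mc == pytest.approx(1 / 200)

    def test_null_p_values_valid_and_mc_near_uniform(self):
        """Random dendrogram labels: p-values must be valid (super-uniform).

        The MC statistic takes many values, so its p-values are near-uniform;
        RF is heavily tied (random pairs usually hit the maximum), so its
        p-values are valid but conservative — asserted as such.
        """
        from scipy.stats import kstest
        rng = np.random.default_rng(6)
        p_rf, p_mc = [], []
        n_reps = 120
        for s in range(n_reps):
            host = simulate_tree(32, seed=10_000 + s)
            labels = sorted(host.tip_labels)
            other = simulate_tree(32, seed=30_000 + s)
            relabel = {a: b for a, b in
                       zip(sorted(other.tip_labels), rng.permutation(labels))}
            t = other.tree
            for leaf in t.leaf_node_iter():
                leaf.taxon.label = relabel[leaf.taxon.label]
            res = congruence_test(host, t, n_permutations=199, seed=s)
            p_rf.append(res.p_rf)
            p_mc.append(res.p_mc)
        se = np.sqrt(0.05 * 0.95 / n_reps)
        for ps in (np.array(p_rf), np.array(p_mc)):
            assert np.mean(ps <= 0.05) <= 0.05 + 3 * se  # never anti-conservative
        assert kstest(p_mc, "uniform").statistic < 0.15

    def test_scores_bounded_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for s in range(20):
            n = int(rng.integers(8, 20))
            a = simulate_tree(n, seed=500 + s)
            b = simulate_tree(n, seed=600 + s)
            res = congruence_test(a, b.tree, n_permutations=99, seed=s)
            assert 0.0 <= res.nrf <= 1.0
            assert 0.0 <= res.nmc <= 1.0

    def test_null_mean_normalization_option(self):
        a = simulate_tree(10, seed=8)
        b = simulate_tree(10, seed=9)
        res = congruence_test(a, b.tree, n_permutations=99, seed=0,
                              normalization="null_mean")
        assert res.normalization == "null_mean"
        assert 0.0 <= res.nmc <= 1.0

    def test_too_few_leaves_errors(self):
        t = rooted_tree("((a,b),c);")
        with pytest.raises(ValueError, match="degenerate"):
            congruence_test(t, rooted_tree("((a,b),c);"), n_permutations=99)
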