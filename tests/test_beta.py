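import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from coralmicro.beta import (CommunityDistance, bray_curtis, classical_mds,
                             kruskal_stress, nmds, pairwise_permanova,
                             permanova, upgma)
from coralmicro.tables_io import RelAbundanceTable, to_relative_abundance


def _dm(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [f"S{i}" for i in range(matrix.shape[0])]
    return CommunityDistance(ids, matrix)


def _random_rel(rng, n_otus=25, n_samples=12):
    vals = rng.random((n_otus, n_samples)) ** 3
    vals /= vals.sum(axis=0)
    return RelAbundanceTable([f"O{i}" for i in range(n_otus)],
                             [f"S{j}" for j in range(n_samples)], vals)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        r = RelAbundanceTable(["A", "B"], ["S1", "S2"],
                              np.array([[0.4, 0.4], [0.6, 0.6]]))
        assert bray_curtis(r).d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        r = RelAbundanceTable(["A", "B"], ["S1", "S2"],
                              np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert bray_curtis(r).d[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        r = RelAbundanceTable(["A", "B", "C"], ["S1", "S2"],
                              np.array([[0.5, 0.25], [0.5, 0.25], [0.0, 0.5]]))
        assert bray_curtis(r).d[0, 1] == pytest.approx(0.5)

    def test_symmetric_zero_diag_in_range(self, rng):
        dm = bray_curtis(_random_rel(rng))
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert dm.d.max() <= 1.0 + 1e-12


def _brute_force_pseudo_f(d, labels):
    """Direct evaluation of the one-way pseudo-F sums of squares."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(d[i, j] ** 2 for i, j in itertools.combinations(range(n), 2)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_within += sum(d[i, j] ** 2
                         for i, j in itertools.combinations(idx, 2)) / len(idx)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _structured_dm(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        return _dm(d)

    def test_hand_example_f_161(self):
        res = permanova(self._structured_dm(), ["A", "A", "B", "B"], m=99, seed=0)
        assert res.pseudo_F == pytest.approx(161.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            x = rng.random((9, 4))
            d = squareform(pdist(x))
            labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
            res = permanova(_dm(d), labels, m=99, seed=1)
            assert res.pseudo_F == pytest.approx(_brute_force_pseudo_f(d, labels))

    def test_matches_skbio_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        r = _random_rel(rng, n_otus=30, n_samples=10)
        dm = bray_curtis(r)
        labels = ["g1"] * 5 + ["g2"] * 5
        mine = permanova(dm, labels, m=99, seed=0)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.d, dm.sample_ids), labels,
            permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"])

    def test_label_name_invariance(self):
        dm = self._structured_dm()
        f1 = permanova(dm, ["A", "A", "B", "B"], m=99, seed=5).pseudo_F
        f2 = permanova(dm, ["xx", "xx", "yy", "yy"], m=99, seed=5).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_p_value_estimator_never_zero(self):
        res = permanova(self._structured_dm(), ["A", "A", "B", "B"], m=999, seed=0)
        assert 0 < res.p_value <= 1
        assert res.p_value >= 1 / (999 + 1)

    def test_rejects_structured_host_effect(self, small_study):
        table, meta, _, _ = small_study
        dm = bray_curtis(to_relative_abundance(table))
        labels = [meta.host_of(s) for s in dm.sample_ids]
        res = permanova(dm, labels, m=999, seed=0)
        assert res.p_value < 0.01

    def test_errors(self):
        dm = self._structured_dm()
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["A", "B", "B", "B"], m=99)
        with pytest.raises(ValueError, match="permutations"):
            permanova(dm, ["A", "A", "B", "B"], m=50)
        const = _dm(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            permanova(const, ["A", "A", "B", "B"], m=99)


class TestPairwisePermanova:
    def test_pair_count(self, rng):
        n_groups = 5
        x = rng.random((n_groups * 3, 4))
        labels = [f"g{i // 3}" for i in range(n_groups * 3)]
        dm = _dm(squareform(pdist(x)))
        res = pairwise_permanova(dm, labels, m=99, seed=0)
        assert len(res) == n_groups * (n_groups - 1) // 2

    def test_pair_equals_subset_permanova(self, rng):
        x = rng.random((9, 4))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dm = _dm(squareform(pdist(x)))
        res = pairwise_permanova(dm, labels, m=99, seed=0)
        ab = next(r for r in res if "a-vs-b" in r.factor)
        direct = permanova(dm.submatrix([f"S{i}" for i in range(6)]),
                           ["a"] * 3 + ["b"] * 3, m=99, seed=0)
        assert ab.pseudo_F == pytest.approx(direct.pseudo_F)


class TestNmds:
    def test_exactly_embeddable_configuration(self, rng):
        pts = rng.random((8, 2)) * 3
        dm = _dm(squareform(pdist(pts)))
        res = nmds(dm, dims=2, n_restarts=4, seed=0)
        assert res.stress < 0.01

    def test_stress_rotation_invariant(self, rng):
        pts = rng.random((7, 2))
        dm = _dm(squareform(pdist(rng.random((7, 5)))))
        res = nmds(dm, dims=2, n_restarts=2, seed=0)
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        s0 = kruskal_stress(dm, res.coords)
        s1 = kruskal_stress(dm, res.coords @ rot + 2.5)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_best_stress_non_increasing_in_restarts(self, rng):
        dm = _dm(squareform(pdist(rng.random((10, 6)))))
        s1 = nmds(dm, n_restarts=1, seed=3).stress
        s5 = nmds(dm, n_restarts=5, seed=3).stress
        assert s5 <= s1 + 1e-12

    def test_degenerate_rejected(self):
        const = _dm(np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="degenerate"):
            nmds(const)

    def test_too_few_samples(self, rng):
        dm = _dm(squareform(pdist(rng.random((3, 2)))))
        with pytest.raises(ValueError, match="samples"):
            nmds(dm, dims=2)

    def test_classical_mds_recovers_euclidean(self, rng):
        pts = rng.random((6, 2))
        d = squareform(pdist(pts))
        coords = classical_mds(d, 2)
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)


class TestUpgma:
    def test_two_samples_join_at_half_distance(self):
        tree = upgma(_dm([[0, 0.4], [0.4, 0]], ids=["A", "B"]))
        assert tree.merges == [(("A",), ("B",), 0.2)]
        assert tree.newick == "(A:0.2,B:0.2);"

    def test_three_sample_hand_example(self):
        d = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        tree = upgma(_dm(d, ids=["A", "B", "C"]))
        (m1, m2) = tree.merges
        assert set(m1[0] + m1[1]) == {"A", "B"} and m1[2] == pytest.approx(0.1)
        assert m2[2] == pytest.approx(0.4)

    def test_ultrametric_leaf_depths(self, rng):
        d = squareform(pdist(rng.random((8, 4))))
        tree = upgma(_dm(d))
        root_height = tree.merges[-1][2]
        coph = tree.cophenetic()
        # every leaf pair split at the root has cophenetic distance 2*root height
        left, right, _ = tree.merges[-1]
        for a in left:
            for b in right:
                assert coph[frozenset((a, b))] == pytest.approx(2 * root_height)

    def test_cophenetic_matches_scipy_average_linkage(self, rng):
        for _ in range(5):
            x = rng.random((9, 5))
            condensed = pdist(x)
            dm = _dm(squareform(condensed))
            tree = upgma(dm)
            coph = tree.cophenetic()
            ref = squareform(cophenet(linkage(condensed, method="average")))
            for i, j in itertools.combinations(range(9), 2):
                assert coph[frozenset((f"S{i}", f"S{j}"))] == \
                    pytest.approx(ref[i, j])
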