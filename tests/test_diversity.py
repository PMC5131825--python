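"""PAM clustering, silhouettes, profile-count estimation, motif distance and
cross-parameter correlation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from zfdiv.diversity import (
    ClusteringSummary,
    DistanceMatrix,
    cross_parameter_correlation,
    distance_from_similarity,
    estimate_profile_count,
    hierarchical_cluster,
    mean_silhouette,
    motif_distance,
    pam_cluster,
)
from zfdiv.intervals import SimilarityMatrix
from zfdiv.motifs import PWM


def _planted(rng, sizes, within=0.15, between=0.6, noise=0.03):
    """Distance matrix with planted clusters; separation = between/within."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    D += rng.normal(0, noise, (n, n))
    D = np.abs((D + D.T) / 2)
    np.fill_diagonal(D, 0)
    return DistanceMatrix(labels=[f"e{i}" for i in range(n)], values=D), labels


class TestPamCluster:
    def test_two_separated_groups(self, rng):
        d, truth = _planted(rng, [8, 7])
        _, assign = pam_cluster(d, 2)
        # agreement up to label permutation
        same = (assign == assign[0]).astype(int)
        truth_b = (truth == truth[0]).astype(int)
        assert np.array_equal(same, truth_b)

    def test_matches_exhaustive_minimum_n6(self, rng):
        # structured toy matrices (the oracle: brute force over all C(6,k)
        # medoid sets); on cluster-structured data BUILD+SWAP attains the
        # global optimum
        for seed in range(5):
            r = np.random.default_rng(seed)
            for sizes, k in (([3, 3], 2), ([2, 2, 2], 3)):
                d, _ = _planted(r, sizes, within=0.1, between=0.7, noise=0.05)
                medoids, assign = pam_cluster(d, k)
                D = d.values
                got = D[:, medoids].min(axis=1).sum()
                best = min(
                    D[:, list(c)].min(axis=1).sum()
                    for c in itertools.combinations(range(6), k)
                )
                assert got == pytest.approx(best)

    def test_k_n_minus_one(self, rng):
        d, _ = _planted(rng, [3, 3])
        medoids, assign = pam_cluster(d, 5)
        non_medoid = [i for i in range(6) if i not in medoids]
        assert len(non_medoid) == 1
        obj = d.values[:, medoids].min(axis=1).sum()
        assert obj == pytest.approx(d.values[non_medoid[0], medoids].min())

    def test_invalid_k(self, rng):
        d, _ = _planted(rng, [3, 3])
        with pytest.raises(ValueError):
            pam_cluster(d, 1)
        with pytest.raises(ValueError):
            pam_cluster(d, 6)

    def test_relabeling_invariance(self, rng):
        d, _ = _planted(rng, [5, 5, 5])
        perm = rng.permutation(15)
        d2 = DistanceMatrix(
            labels=[d.labels[i] for i in perm], values=d.values[np.ix_(perm, perm)]
        )
        _, a1 = pam_cluster(d, 3)
        _, a2 = pam_cluster(d2, 3)
        # partitions agree after mapping back
        part1 = {frozenset(np.where(a1 == c)[0]) for c in set(a1)}
        part2 = {frozenset(perm[np.where(a2 == c)[0]]) for c in set(a2)}
        assert part1 == part2


class TestMeanSilhouette:
    def test_tight_distant_clusters_near_one(self, rng):
        d, truth = _planted(rng, [6, 6], within=0.02, between=0.9, noise=0.001)
        assert mean_silhouette(d, truth) > 0.9

    def test_equidistant_points_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        d = DistanceMatrix(labels=list("abcdef"), values=D)
        assert mean_silhouette(d, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.0)

    def test_hand_computed_five_points(self):
        # clusters {0,1} and {2,3,4}
        D = np.array(
            [
                [0.0, 1.0, 4.0, 5.0, 6.0],
                [1.0, 0.0, 3.0, 4.0, 5.0],
                [4.0, 3.0, 0.0, 1.0, 2.0],
                [5.0, 4.0, 1.0, 0.0, 1.0],
                [6.0, 5.0, 2.0, 1.0, 0.0],
            ]
        )
        d = DistanceMatrix(labels=list("abcde"), values=D)
        lab = np.array([0, 0, 1, 1, 1])
        # s(0) = (5-1)/5 = 0.8 ; s(1) = (4-1)/4 = 0.75
        # s(2): a=1.5, b=3.5 -> 2/3.5 ; s(3): a=1, b=4.5 -> 3.5/4.5
        # s(4): a=1.5, b=5.5 -> 4/5.5
        expected = np.mean([0.8, 0.75, 2 / 3.5, 3.5 / 4.5, 4 / 5.5])
        assert mean_silhouette(d, lab) == pytest.approx(expected)

    def test_singleton_cluster_scores_zero(self):
        D = np.array([[0, 1, 9], [1, 0, 9], [9, 9, 0]], dtype=float)
        d = DistanceMatrix(labels=list("abc"), values=D)
        val = mean_silhouette(d, np.array([0, 0, 1]))
        # singleton c contributes 0; a and b have a=1, b=9 -> 8/9 each
        assert val == pytest.approx((8 / 9 + 8 / 9 + 0) / 3)

    def test_matches_sklearn_to_1e10(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            d = DistanceMatrix(labels=[str(i) for i in range(n)], values=D)
            k = int(rng.integers(2, 5))
            lab = rng.integers(0, k, n)
            while len(np.unique(lab)) < 2 or np.min(np.bincount(lab, minlength=k)[np.unique(lab)]) < 2:
                lab = rng.integers(0, k, n)
            ours = mean_silhouette(d, lab)
            ref = silhouette_score(D, lab, metric="precomputed")
            assert ours == pytest.approx(ref, abs=1e-10)


class TestEstimateProfileCount:
    def test_planted_four_clusters_recovered(self, rng):
        d, _ = _planted(rng, [8, 8, 8, 8])
        s = estimate_profile_count(d, k_max=10)
        assert s.estimated_k == 4
        assert s.mean_silhouettes[s.k_values.index(s.estimated_k)] >= 0.95 * s.max_silhouette

    def test_degenerate_all_zero(self):
        d = DistanceMatrix(labels=list("abcdef"), values=np.zeros((6, 6)))
        s = estimate_profile_count(d, k_max=4)
        assert s.degenerate
        assert s.estimated_k == 4

    def test_n3_single_k(self, rng):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        d = DistanceMatrix(labels=list("abc"), values=D)
        s = estimate_profile_count(d, k_max=2)
        assert s.k_values == [2]
        assert s.estimated_k == 2

    def test_hierarchical_agrees_on_well_separated(self, rng):
        d, truth = _planted(rng, [10, 10, 10], within=0.05, between=0.9, noise=0.01)
        lab = hierarchical_cluster(d, 3)
        _, pam_lab = pam_cluster(d, 3)
        part_h = {frozenset(np.where(lab == c)[0]) for c in set(lab)}
        part_p = {frozenset(np.where(pam_lab == c)[0]) for c in set(pam_lab)}
        assert part_h == part_p


def _pwm(cons):
    mat = np.full((len(cons), 4), 0.04)
    for i, c in enumerate(cons):
        mat[i, "ACGT".index(c)] = 0.88
    return PWM(name=cons, matrix=mat)


class TestMotifDistance:
    def test_identical_zero(self):
        p = _pwm("ACGTAG")
        assert motif_distance(p, p) == pytest.approx(0.0)

    def test_reverse_complement_zero(self):
        p = _pwm("ACGTAG")
        assert motif_distance(p, p.reverse_complement()) == pytest.approx(0.0)

    def test_matches_exhaustive_offset_oracle(self):
        a, b = _pwm("ACGTAG"), _pwm("CGTAGA")
        best = -np.inf
        for mat in (b.matrix, b.reverse_complement().matrix):
            for off in range(-2, 3):
                i0, i1 = max(0, off), min(6, off + 6)
                if i1 - i0 < 4:
                    continue
                cols = []
                for i in range(i0, i1):
                    x, y = a.matrix[i], mat[i - off]
                    cols.append(np.corrcoef(x, y)[0, 1])
                best = max(best, np.mean(cols))
        assert motif_distance(a, b) == pytest.approx(1 - best)

    def test_range_bounds(self, rng):
        for _ in range(10):
            a = _pwm("".join(rng.choice(list("ACGT"), 8)))
            b = _pwm("".join(rng.choice(list("ACGT"), 6)))
            d = motif_distance(a, b)
            assert 0 <= d <= 2


class TestCrossParameterCorrelation:
    def _sim(self, rng, labels, kind="pearson"):
        n = len(labels)
        v = rng.uniform(-0.5, 1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1)
        return SimilarityMatrix(labels=labels, values=v, value_kind=kind)

    def test_self_correlation_one(self, rng):
        labels = [f"p{i}" for i in range(8)]
        s = self._sim(rng, labels)
        out = cross_parameter_correlation({"a": s, "b": s})
        assert out.loc["a", "b"] == pytest.approx(1.0)

    def test_linear_transform_perfect(self, rng):
        labels = [f"p{i}" for i in range(8)]
        s = self._sim(rng, labels)
        t = SimilarityMatrix(labels=labels, values=0.5 * s.values + 0.2,
                             value_kind="pearson")
        out = cross_parameter_correlation({"a": s, "b": t})
        assert out.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(900 + s)
            labels = [f"p{i}" for i in range(50)]
            out = cross_parameter_correlation(
                {"a": self._sim(rng, labels), "b": self._sim(rng, labels)}
            )
            hits += abs(out.loc["a", "b"]) < 0.3
        assert hits >= 0.95 * n_seeds

    def test_pair_subset_restriction(self, rng):
        labels = [f"p{i}" for i in range(6)]
        a, b = self._sim(rng, labels), self._sim(rng, labels)
        pairs = [("p0", "p1"), ("p2", "p3"), ("p4", "p5"), ("p0", "p2")]
        out = cross_parameter_correlation({"a": a, "b": b}, pair_subset=pairs)
        assert out.shape == (2, 2)

    def test_too_few_pairs_rejected(self, rng):
        labels = ["p0", "p1", "p2"]
        a = self._sim(rng, labels)
        with pytest.raises(ValueError, match="3 usable"):
            cross_parameter_correlation({"a": a}, pair_subset=[("p0", "p1")])


class TestSequenceDistance:
    def test_identical_sequences_zero(self):
        from zfdiv.diversity import sequence_distance

        assert sequence_distance("MKVLAA", "MKVLAA") == pytest.approx(0.0)

    def test_unrelated_sequences_large(self):
        from zfdiv.diversity import sequence_distance

        d = sequence_distance("MMMMMMMMMM", "WWWWWWWWWW")
        assert d == pytest.approx(1.0)

    def test_partial_identity(self):
        from zfdiv.diversity import sequence_distance

        # 5 of 10 positions match after trivial global alignment
        assert sequence_distance("AAAAAWWWWW", "AAAAAYYYYY") == pytest.approx(0.5)


class TestDistanceFromSimilarity:
    def test_jaccard_conversion(self, rng):
        labels = list("abcd")
        v = rng.uniform(0, 1, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1)
        sim = SimilarityMatrix(labels=labels, values=v, value_kind="jaccard")
        d = distance_from_similarity(sim, source_kind="peaks")
        assert np.allclose(d.values, 1 - v, atol=1e-12) or np.allclose(np.diag(d.values), 0)
        assert d.values[0, 1] == pytest.approx(1 - v[0, 1])
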