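"""Validity-index battery against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prototyper as pt
from prototyper.engines import ClusterSolution

from conftest import (
    oracle_adjusted_rand,
    oracle_c_index,
    oracle_gdi31,
    oracle_kappa,
    oracle_pair_comparisons,
    oracle_point_biserial,
    oracle_rand,
    oracle_silhouette,
    random_labeled_instance,
)


class TestAlignment:
    def test_relabeling_recovered(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([7, 7, 5, 5, 9, 9])
        mapping = pt.align_labels(a, b)
        assert mapping == {7: 1, 5: 2, 9: 3}

    def test_contingency_8219_identity(self):
        # contingency [[8,2],[1,9]]: identity beats the swap (17 vs 3)
        a = np.array([1] * 10 + [2] * 10)
        b = np.array([1] * 8 + [2] * 2 + [1] * 1 + [2] * 9)
        mapping = pt.align_labels(a, b)
        assert mapping == {1: 1, 2: 2}

    def test_extra_cluster_padded(self):
        a = np.array([1, 1, 2, 2, 2, 2])
        b = np.array([1, 1, 2, 2, 3, 3])
        mapping = pt.align_labels(a, b)
        assert set(mapping) == {1, 2, 3}
        assert sorted(mapping.values())[:2] == [1, 2]
        # the surplus b-cluster maps to a fresh label outside a's
        assert set(mapping.values()) - {1, 2}


class TestKappa:
    def test_identical_partitions(self):
        a = np.array([1, 2, 3, 1, 2, 3])
        assert pt.cohen_kappa(a, a) == 1.0

    def test_hand_confusion_value(self):
        # confusion [[2,1],[1,2]] on n=6: p_o=4/6, p_e=1/2, kappa=1/3
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([1, 1, 2, 2, 2, 1])
        assert pt.cohen_kappa(a, b, aligned=True) == pytest.approx(1 / 3)

    def test_alignment_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 4, size=50)
        perm = {1: 3, 2: 1, 3: 2}
        b = np.array([perm[v] for v in a])
        assert pt.cohen_kappa(a, b) == 1.0

    def test_single_category_degenerate(self):
        a = np.ones(5, dtype=int)
        assert pt.cohen_kappa(a, a, aligned=True) == 1.0

    def test_matches_oracle_after_alignment(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(1, 4, size=40)
            b = rng.integers(1, 4, size=40)
            b_aligned = pt.apply_mapping(b, pt.align_labels(a, b))
            assert pt.cohen_kappa(a, b) == pytest.approx(
                oracle_kappa(a, b_aligned), abs=1e-12
            )


class TestRandIndices:
    def test_identical(self):
        a = np.array([1, 1, 2, 2])
        assert pt.rand_index(a, a) == 1.0
        assert pt.adjusted_rand(a, a) == 1.0

    def test_crossed_quartet(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        assert pt.rand_index(a, b) == pytest.approx(2 / 6)
        assert pt.adjusted_rand(a, b) < 0  # worse than chance

    def test_singletons_vs_lump(self):
        a = np.array([1, 2, 3, 4])
        b = np.array([1, 1, 1, 1])
        assert pt.rand_index(a, b) == 0.0

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.integers(1, 4, size=30)
            b = rng.integers(1, 4, size=30)
            assert pt.rand_index(a, b) == pytest.approx(oracle_rand(a, b))
            assert pt.adjusted_rand(a, b) == pytest.approx(
                oracle_adjusted_rand(a, b), abs=1e-12
            )

    def test_adjusted_rand_null_centered(self):
        rng = np.random.default_rng(5)
        values = [
            pt.adjusted_rand(rng.integers(1, 5, 200), rng.integers(1, 5, 200))
            for _ in range(300)
        ]
        assert abs(np.mean(values)) < 0.02


class TestPairCounts:
    def test_worked_instance(self, two_far_clusters):
        x, labels = two_far_clusters
        pc = pt.pair_counts(x, labels)
        assert (pc.n_w, pc.n_b, pc.n_t) == (2, 4, 6)
        assert (pc.s_plus, pc.s_minus) == (8, 0)

    def test_all_identical_points_tie(self):
        x = np.zeros((6, 2))
        labels = np.array([1, 1, 1, 2, 2, 2])
        pc = pt.pair_counts(x, labels)
        assert pc.s_plus == pc.s_minus == 0

    def test_invariant_bounds_enforced(self):
        with pytest.raises(ValueError):
            pt.PairCounts(s_plus=9, s_minus=0, n_w=2, n_b=4, n_t=6)
        with pytest.raises(ValueError):
            pt.PairCounts(s_plus=0, s_minus=0, n_w=2, n_b=5, n_t=6)


class TestGammaGPlus:
    def test_perfect_separation(self):
        gamma, g_plus = pt.gamma_gplus(
            pt.PairCounts(s_plus=8, s_minus=0, n_w=2, n_b=4, n_t=6)
        )
        assert gamma == 1.0
        assert g_plus == 0.0

    def test_symmetry_zero(self):
        gamma, _ = pt.gamma_gplus(
            pt.PairCounts(s_plus=3, s_minus=3, n_w=2, n_b=4, n_t=6)
        )
        assert gamma == 0.0

    def test_all_tied_gamma_missing(self):
        gamma, g_plus = pt.gamma_gplus(
            pt.PairCounts(s_plus=0, s_minus=0, n_w=2, n_b=4, n_t=6)
        )
        assert np.isnan(gamma)
        assert g_plus == 0.0


class TestCIndex:
    def test_worked_instance_zero(self, two_far_clusters):
        x, labels = two_far_clusters
        assert pt.c_index(x, labels) == pytest.approx(0.0)

    def test_worst_pairing_is_one(self):
        # the single within pair is the largest distance overall
        x = np.array([[0.0], [100.0], [50.0]])
        labels = np.array([1, 1, 2])
        assert pt.c_index(x, labels) == pytest.approx(1.0)


class TestGDI31:
    def test_worked_instance(self, two_far_clusters):
        x, labels = two_far_clusters
        # cross distances 10, 11, 9, 10 -> mean 10; max diameter 1
        assert pt.gdi31(x, labels) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x, labels = random_labeled_instance(rng)
        assert pt.gdi31(3.7 * x, labels) == pytest.approx(pt.gdi31(x, labels))

    def test_all_singletons_missing(self):
        x = np.array([[0.0], [1.0], [5.0]])
        assert np.isnan(pt.gdi31(x, np.array([1, 2, 3])))


class TestPointBiserial:
    def test_equals_pair_correlation(self, two_far_clusters):
        x, labels = two_far_clusters
        value = pt.point_biserial(x, labels)
        assert value > 0
        assert value == pytest.approx(oracle_point_biserial(x, labels))

    def test_sign_tracks_separation_quality(self):
        # positive when within pairs are close, negative when they are far
        x = np.array([[0.0], [10.0], [0.1], [10.1]])
        good = np.array([1, 2, 1, 2])
        bad = np.array([1, 1, 2, 2])
        assert pt.point_biserial(x, good) > 0
        assert pt.point_biserial(x, bad) < 0
        # and each equals the pair-level correlation, which is antisymmetric
        # under exchanging the within/between roles of the indicator
        assert pt.point_biserial(x, bad) == pytest.approx(
            oracle_point_biserial(x, bad)
        )

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(9)
        values = []
        for _ in range(200):
            x = rng.normal(size=(20, 2))
            labels = rng.integers(1, 3, size=20)
            if len(set(labels)) < 2:
                continue
            values.append(pt.point_biserial(x, labels))
        assert abs(np.mean(values)) < 0.02


class TestSilhouette:
    def test_worked_instance(self, two_far_clusters):
        # per point: outer points have b = 10.5, inner points b = 9.5
        # mean of (9.5/10.5, 8.5/9.5, 8.5/9.5, 9.5/10.5)
        x, labels = two_far_clusters
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert pt.silhouette_mean(x, labels) == pytest.approx(expected)
        assert pt.silhouette_mean(x, labels) == pytest.approx(
            oracle_silhouette(x, labels)
        )

    def test_coincident_clusters_near_zero(self):
        rng = np.random.default_rng(1)
        x = np.tile(rng.normal(size=(20, 2)), (2, 1))
        labels = np.repeat([1, 2], 20)
        assert abs(pt.silhouette_mean(x, labels)) < 0.05


class TestSDbw:
    def test_tight_separated_small(self):
        rng = np.random.default_rng(4)
        x = np.vstack([
            rng.normal(0, 0.01, size=(30, 2)),
            rng.normal(50, 0.01, size=(30, 2)),
        ])
        labels = np.repeat([1, 2], 30)
        assert pt.s_dbw(x, labels) < 0.05

    def test_merging_true_clusters_increases(self):
        rng = np.random.default_rng(8)
        x = np.vstack([
            rng.normal(0, 0.3, size=(40, 2)),
            rng.normal(5, 0.3, size=(40, 2)),
            rng.normal(10, 0.3, size=(40, 2)),
        ])
        truth = np.repeat([1, 2, 3], 40)
        merged = truth.copy()
        # split the merged pair randomly to keep k constant
        merged[merged == 3] = 2
        merged[:20] = 3
        assert pt.s_dbw(x, merged) > pt.s_dbw(x, truth)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        x, labels = random_labeled_instance(rng)
        assert pt.s_dbw(x + 13.5, labels) == pytest.approx(pt.s_dbw(x, labels))


class TestPartitionAicBic:
    def test_lpa_k1_closed_form(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(300, 5))
        sol = pt.lpa_fit(x, 1, families=("full",), seed=0)
        aic, bic = pt.partition_aic_bic(x, sol)
        # single-Gaussian MLE log-likelihood, closed form
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, bias=True)
        sign, logdet = np.linalg.slogdet(cov)
        n, d = x.shape
        loglik = -0.5 * n * (d * np.log(2 * np.pi) + logdet + d)
        p = d + d * (d + 1) / 2
        assert aic == pytest.approx(-2 * loglik + 2 * p, abs=1e-6)
        assert bic == pytest.approx(-2 * loglik + p * np.log(n), abs=1e-6)

    def test_bic_aic_penalty_arithmetic(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=(100, 5)) + np.repeat([0, 8], 50)[:, None]
        sol = pt.ward_kmeans(x, 2, seed=0)
        aic, bic = pt.partition_aic_bic(x, sol)
        p = 5 * 2 + 1 + 1
        assert bic - aic == pytest.approx(p * (np.log(100) - 2))

    def test_hard_partition_bic_minimized_at_truth(self):
        rng = np.random.default_rng(23)
        centers = rng.normal(scale=8, size=(5, 5))
        x = np.vstack([c + rng.normal(scale=0.5, size=(80, 5)) for c in centers])
        bics = {}
        for k in range(3, 11):
            sol = pt.ward_kmeans(x, k, seed=0)
            bics[k] = pt.partition_aic_bic(x, sol)[1]
        assert min(bics, key=bics.get) == 5


class TestOracleEquivalence:
    """Pair-based indices equal naive pair-enumeration on random instances."""

    def test_random_instances(self):
        rng = np.random.default_rng(20240901)
        for _ in range(40):
            x, labels = random_labeled_instance(rng)
            s_plus, s_minus, within, between = oracle_pair_comparisons(x, labels)
            pc = pt.pair_counts(x, labels)
            assert (pc.s_plus, pc.s_minus) == (s_plus, s_minus)
            assert (pc.n_w, pc.n_b) == (len(within), len(between))
            assert pt.c_index(x, labels) == pytest.approx(
                oracle_c_index(x, labels), abs=1e-10
            )
            assert pt.gdi31(x, labels) == pytest.approx(
                oracle_gdi31(x, labels), abs=1e-10
            )
            assert pt.point_biserial(x, labels) == pytest.approx(
                oracle_point_biserial(x, labels), abs=1e-10
            )
            assert pt.silhouette_mean(x, labels) == pytest.approx(
                oracle_silhouette(x, labels), abs=1e-10
            )

    def test_person_reordering_invariance(self):
        rng = np.random.default_rng(77)
        x, labels = random_labeled_instance(rng)
        perm = rng.permutation(len(x))
        for fn in (pt.c_index, pt.gdi31, pt.point_biserial,
                   pt.silhouette_mean, pt.s_dbw):
            assert fn(x[perm], labels[perm]) == pytest.approx(
                fn(x, labels), abs=1e-9
            )


class TestPairCountProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31),
           st.integers(min_value=6, max_value=14))
    def test_counts_match_oracle_and_respect_bounds(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 2))
        labels = rng.integers(1, 3, size=n)
        if len(set(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        s_plus, s_minus, within, between = oracle_pair_comparisons(x, labels)
        pc = pt.pair_counts(x, labels)
        assert (pc.s_plus, pc.s_minus) == (s_plus, s_minus)
        assert pc.s_plus + pc.s_minus <= pc.n_w * pc.n_b
        assert pc.n_t == n * (n - 1) // 2
        gamma, g_plus = pt.gamma_gplus(pc)
        if not np.isnan(gamma):
            assert -1.0 <= gamma <= 1.0
        assert g_plus >= 0.0


class TestMonotoneSanity:
    def test_truth_beats_merged_on_every_index(self):
        """On separated blobs the truth-k partition wins each index in its
        stated direction against a merged-k partition."""
        rng = np.random.default_rng(31)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        x = np.vstack([c + rng.normal(scale=0.4, size=(40, 2)) for c in centers])
        truth = np.repeat([1, 2, 3, 4], 40)
        merged = truth.copy()
        merged[merged == 4] = 3
        for name, fn in [
            ("c_index", pt.c_index), ("gdi31", pt.gdi31),
            ("point_biserial", pt.point_biserial),
            ("silhouette", pt.silhouette_mean), ("s_dbw", pt.s_dbw),
        ]:
            good, bad = fn(x, truth), fn(x, merged)
            if pt.INDEX_DIRECTIONS[name] == "min":
                assert good < bad, name
            else:
                assert good > bad, name
        g_truth = pt.gamma_gplus(pt.pair_counts(x, truth))
        g_merged = pt.gamma_gplus(pt.pair_counts(x, merged))
        assert g_truth[0] > g_merged[0]  # gamma: max
        assert g_truth[1] < g_merged[1]  # g_plus: min


class TestValidityReport:
    def test_directions_table(self, two_far_clusters):
        x, labels = two_far_clusters
        solution = ClusterSolution(
            algorithm="ward_kmeans", k=2, labels=labels,
            centers=np.array([[0.5], [10.5]]), sizes=np.array([2, 2]),
        )
        report = pt.compute_validity(x, solution, comparison=labels)
        assert report["kappa"] == 1.0
        table = pt.validity_table({"toy": report})
        assert table.loc["c_index", "direction"] == "min"
        assert table.loc["silhouette", "direction"] == "max"
        assert set(report) >= set(pt.INDEX_DIRECTIONS)
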