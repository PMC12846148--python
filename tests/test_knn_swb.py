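import numpy as np
import pytest

from conftest import make_feats, random_feats
from swblab.exceptions import EmptyDatasetError, ValidationError
from swblab.io_core import N_BANDS, N_CHANNELS
from swblab.knn_swb import (
    LabeledInstance,
    best_combination,
    binomial_winner_test,
    build_instances,
    chi_squared_gof,
    drop_singleton_labels,
    dtw_distance,
    evaluate_scheme,
    loo_1nn,
    mse,
    rescale_mse,
)


def _instances(points, labels):
    return [
        LabeledInstance("P1", i, np.atleast_1d(np.asarray(p, dtype=float)), int(l))
        for i, (p, l) in enumerate(zip(points, labels))
    ]


class TestSingletonRemoval:
    @pytest.mark.parametrize(
        "labels,expected",
        [([5, 5, 6, 6, 9], [5, 5, 6, 6]), ([7, 7, 7], [7, 7, 7])],
    )
    def test_singletons_dropped_order_preserved(self, labels, expected):
        kept = drop_singleton_labels(_instances(range(len(labels)), labels))
        assert [inst.swb for inst in kept] == expected

    def test_all_singletons_is_an_error(self):
        with pytest.raises(EmptyDatasetError):
            drop_singleton_labels(_instances([0, 1, 2], [1, 2, 3]))


class TestLoo1nn:
    def test_hand_case(self):
        inst = _instances([0.0, 1.0, 2.0], [3, 7, 3])
        pred = loo_1nn(inst)
        np.testing.assert_array_equal(pred, [7, 3, 7])
        assert mse([3, 7, 3], pred) == 16.0

    def test_perfect_separation_gives_zero_mse(self):
        inst = _instances([0.0, 0.0, 100.0, 100.0], [2, 2, 9, 9])
        assert mse([i.swb for i in inst], loo_1nn(inst)) == 0.0

    def test_tie_broken_by_smallest_index(self):
        # instance 1 (x=1) is equidistant from 0 and 2; index 0 must win
        inst = _instances([0.0, 1.0, 2.0], [4, 4, 8])
        # need duplicated labels to be realistic but tie rule is index-based
        assert loo_1nn(inst)[1] == 4

    def test_matches_brute_force_scan(self, rng):
        # oracle: explicit all-pairs nearest-neighbour loop
        X = rng.normal(size=(50, 3))
        labels = rng.integers(1, 11, size=50)
        inst = [LabeledInstance("P1", i, X[i], int(labels[i])) for i in range(50)]
        pred = loo_1nn(inst)
        for i in range(50):
            best_j, best_d = -1, np.inf
            for j in range(50):
                if j == i:
                    continue
                d = np.sqrt(((X[i] - X[j]) ** 2).sum())
                if d < best_d:
                    best_d, best_j = d, j
            assert pred[i] == labels[best_j]


class TestMse:
    def test_hand_cases(self):
        assert mse([3, 5], [4, 9]) == 8.5
        assert mse([3], [9]) == 36.0
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_joint_permutation_invariance(self, rng):
        true = rng.integers(1, 11, size=30)
        pred = rng.integers(1, 11, size=30)
        perm = rng.permutation(30)
        assert mse(true, pred) == pytest.approx(mse(true[perm], pred[perm]), abs=1e-12)


def _brute_force_dtw(x, y):
    """Minimum cumulative |x_i - y_j| over all monotone warping paths."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(x[i] - y[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDtw:
    def test_identity_and_hand_case(self):
        assert dtw_distance(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == 0.0
        assert dtw_distance(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])) == 0.0

    def test_bounded_by_euclidean_pointwise_sum(self, rng):
        # the identity path is admissible, so DTW <= sum |x_i - y_i|
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert dtw_distance(x, y) <= np.abs(x - y).sum() + 1e-12

    def test_matches_exhaustive_paths(self, rng):
        for _ in range(20):
            n, m = rng.integers(1, 7, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            assert dtw_distance(x, y) == pytest.approx(_brute_force_dtw(x, y), abs=1e-10)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(2, 8)), rng.normal(size=(2, 5))
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x), abs=1e-12)


class TestEvaluateScheme:
    def test_scheme3_vector_has_70_features(self, rng):
        feats = random_feats(rng)
        inst = build_instances(feats, 3)
        assert inst[0].x.shape == (N_BANDS * N_CHANNELS,)
        assert inst[0].x.shape == (70,)

    def test_constant_reporter_is_rejected(self, rng):
        feats = random_feats(rng)
        feats.swb[:] = 6
        with pytest.raises(EmptyDatasetError):
            evaluate_scheme(feats, 3)

    def test_coupled_band_beats_uncoupled_band(self):
        # strongly gamma-coupled participant: scheme-2 gamma must beat delta
        from swblab.pipelines import cohort_features
        from swblab.synthetic_cohort import CohortSpec, generate_cohort, uniform_coupling

        spec = CohortSpec(
            n_clusters=1,
            participants_per_cluster=1,
            cluster_couplings=[uniform_coupling("gamma", 0.5)],
            session_length_s=60 * 30.0,
            seed=101,
        )
        recs, _ = generate_cohort(spec)
        feats = cohort_features(recs, compute_faa_values=False)[0]
        ev_gamma = evaluate_scheme(feats, 2, band_name="gamma")
        ev_delta = evaluate_scheme(feats, 2, band_name="delta")
        assert ev_gamma.mse < ev_delta.mse


class TestWinners:
    def test_best_combination_unique_and_tied(self, rng):
        feats = random_feats(rng)
        evs = [
            evaluate_scheme(feats, 1, band_name="gamma", channel="AF3"),
            evaluate_scheme(feats, 1, band_name="delta", channel="T7"),
        ]
        winners, unique = best_combination(evs)
        assert len(winners) >= 1
        evs[1].mse = evs[0].mse  # force a tie
        winners, unique = best_combination(evs)
        assert len(winners) == 2 and not unique

    @pytest.mark.parametrize(
        "values,expected",
        [([2.0, 4.0], [0.5, 1.0]), ([3.0], [1.0]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])],
    )
    def test_rescale_mse(self, values, expected):
        np.testing.assert_allclose(rescale_mse(values), expected)


class TestCountTests:
    def test_band_winner_tallies_reject_uniformity(self):
        res = chi_squared_gof([2, 3, 3, 5, 16])
        assert res.chi2 == pytest.approx(23.241, abs=5e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.0001, abs=5e-5)
        assert res.residuals[-1] == pytest.approx(4.24, abs=5e-3)

    def test_time_series_tallies_consistent_with_chance(self):
        res = chi_squared_gof([4, 3, 7, 3, 5, 6])
        assert res.chi2 == pytest.approx(2.857, abs=5e-4)
        assert res.df == 5
        assert res.p == pytest.approx(0.722, abs=5e-4)

    def test_uniform_counts_give_zero_statistic(self):
        res = chi_squared_gof([5, 5, 5, 5, 5])
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_statistic_invariant_to_category_order(self, rng):
        counts = rng.integers(0, 20, size=6) + 1
        a = chi_squared_gof(counts)
        b = chi_squared_gof(counts[rng.permutation(6)])
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_binomial_winner(self):
        res = binomial_winner_test(16, 29, 0.2)
        assert res.p_one_sided < 0.0001
        assert binomial_winner_test(3, 4, 0.5).p_two_sided == pytest.approx(0.625)
        # at the expected count, the upper tail is at least one half
        assert binomial_winner_test(2, 10, 0.2).p_one_sided >= 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            chi_squared_gof([0, 0, 0])
        with pytest.raises(Exception):
            binomial_winner_test(3, 4, 1.5)
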