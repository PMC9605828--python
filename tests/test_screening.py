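"""Outlier screening, Kennard-Stone splitting and cohort statistics."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from nirproline import (
    chauvenet,
    cohort_stats,
    compare_groups,
    dixon_test,
    kennard_stone,
    mahalanobis_distances,
    screen_outliers,
)

from .conftest import make_spectrum_set


class TestMahalanobis:
    def test_perturbed_replicate_has_maximum_distance(self, rng):
        base = rng.normal(size=20)
        x = base[None, :] + 0.01 * rng.normal(size=(12, 20))
        x[7] += 2.0 * rng.normal(size=20)
        d = mahalanobis_distances(make_spectrum_set(x), n_components=3)
        assert int(np.argmax(d)) == 7

    def test_full_rank_scores_reduce_to_classic_mahalanobis(self, rng):
        # with n > p and all components kept, the score-space distance
        # equals the textbook Mahalanobis distance in the original space
        x = rng.normal(size=(30, 5))
        d = mahalanobis_distances(make_spectrum_set(x), n_components=5)
        centered = x - x.mean(axis=0)
        vi = np.linalg.inv(np.cov(x, rowvar=False))
        expected = np.sqrt(np.einsum("ij,jk,ik->i", centered, vi, centered))
        np.testing.assert_allclose(d, expected, rtol=1e-8)

    def test_invariant_under_invertible_affine_maps(self, rng):
        latent = rng.normal(size=(15, 3))
        x = latent @ rng.normal(size=(3, 8))  # rank-3 data in 8 dims
        s1 = make_spectrum_set(x)
        a = rng.normal(size=(8, 8)) + 4 * np.eye(8)
        s2 = make_spectrum_set(x @ a + rng.normal(size=8)[None, :])
        np.testing.assert_allclose(
            mahalanobis_distances(s1, 3), mahalanobis_distances(s2, 3), rtol=1e-8
        )

    def test_too_many_components_rejected(self, rng):
        latent = rng.normal(size=(10, 2))
        s = make_spectrum_set(latent @ rng.normal(size=(2, 6)))
        with pytest.raises(ValueError):
            mahalanobis_distances(s, 5)


class TestDixon:
    def test_textbook_gap_ratio_flags_outlier(self):
        flag, q = dixon_test(np.array([0.10, 0.15, 0.16, 0.17, 0.95]), alpha=0.05)
        assert q == pytest.approx((0.95 - 0.17) / (0.95 - 0.10), abs=1e-12)
        assert q == pytest.approx(0.918, abs=5e-4)
        assert flag

    def test_equal_values_give_zero_statistic(self):
        flag, q = dixon_test(np.array([2.0] * 5))
        assert q == 0.0 and not flag

    def test_uniform_sequence_not_flagged(self):
        flag, q = dixon_test(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), alpha=0.05)
        assert not flag and q == pytest.approx(0.25)

    @pytest.mark.parametrize("n", [2, 31])
    def test_sample_size_outside_table_rejected(self, n):
        with pytest.raises(ValueError):
            dixon_test(np.arange(n, dtype=float))

    def test_low_extreme_also_detected(self):
        flag, q = dixon_test(np.array([-5.0, 0.83, 0.84, 0.85, 0.86]), alpha=0.05)
        assert flag and q > 0.9


class TestChauvenet:
    def test_far_point_flagged_in_ten(self):
        values = np.array([0.0] * 9 + [10.0])
        flags = chauvenet(values)
        assert flags[-1] and not flags[:-1].any()

    def test_all_equal_flags_nothing(self):
        assert not chauvenet(np.full(6, 1.5)).any()

    def test_moderate_point_in_four_not_flagged(self):
        # z ~ 0.87 at n=4: expected count 4 * 2 * sf(0.87) ~ 1.5 >> 1/2
        assert not chauvenet(np.array([0.0, 0.0, 2.0, 2.0])).any()

    def test_matches_expected_count_rule(self, rng):
        values = rng.normal(size=25)
        values[3] = 8.0
        z = np.abs(values - values.mean()) / values.std(ddof=1)
        expected = values.size * 2 * stats.norm.sf(z) < 0.5
        np.testing.assert_array_equal(chauvenet(values), expected)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            chauvenet(np.array([1.0, 2.0, 3.0]))


def ks_oracle_order(x: np.ndarray, n_cal: int) -> list[int]:
    """Independent step-by-step Kennard-Stone: explicit argmax loops."""
    n = x.shape[0]
    dist = cdist(x, x)
    best = (-1.0, (0, 1))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > best[0]:
                best = (dist[i, j], (i, j))
    selected = list(best[1])
    while len(selected) < n_cal:
        cand_best, cand_idx = -1.0, -1
        for k in range(n):
            if k in selected:
                continue
            mind = min(dist[k, s] for s in selected)
            if mind > cand_best:
                cand_best, cand_idx = mind, k
        selected.append(cand_idx)
    return selected


class TestKennardStone:
    def test_one_dimensional_worked_example(self):
        # effectively 1-D geometry: both columns carry the same coordinate
        s = make_spectrum_set(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [10.0, 10.0]]))
        split = kennard_stone(s, 3)
        assert sorted(split.calibration_ids) == ["s0", "s2", "s3"]
        assert split.validation_ids == ["s1"]

    def test_complement_when_all_but_one_selected(self, rng):
        s = make_spectrum_set(rng.normal(size=(6, 4)))
        split = kennard_stone(s, 5)
        assert len(split.validation_ids) == 1
        assert set(split.calibration_ids) | set(split.validation_ids) == set(s.sample_ids)

    def test_duplicates_selected_last(self, rng):
        x = rng.normal(size=(5, 3))
        s = make_spectrum_set(np.vstack([x, x[0]]))  # row 5 duplicates row 0
        split = kennard_stone(s, 5)
        assert "s5" in split.validation_ids or "s0" in split.validation_ids

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        x = rng.normal(size=(n, 4))
        s = make_spectrum_set(x)
        for n_cal in range(2, n):
            expected = {f"s{i}" for i in ks_oracle_order(x, n_cal)}
            assert set(kennard_stone(s, n_cal).calibration_ids) == expected

    def test_out_of_range_sizes_rejected(self, rng):
        s = make_spectrum_set(rng.normal(size=(5, 3)))
        for bad in (1, 5, 6):
            with pytest.raises(ValueError):
                kennard_stone(s, bad)


class TestCohortStats:
    def test_calibration_cohort_cv(self):
        # two-point vector with prescribed mean and SD
        mean, sd = 0.005296, 0.001897
        values = np.array([mean + sd / np.sqrt(2), mean - sd / np.sqrt(2)])
        st_ = cohort_stats(values)
        assert st_.mean == pytest.approx(mean)
        assert st_.sd == pytest.approx(sd)
        assert st_.cv == pytest.approx(0.3581, abs=1e-4)

    def test_validation_cohort_cv(self):
        mean, sd = 0.005213, 0.001832
        values = np.array([mean + sd / np.sqrt(2), mean - sd / np.sqrt(2)])
        assert round(cohort_stats(values).cv, 4) == 0.3514

    def test_constant_cohort_has_zero_cv(self):
        st_ = cohort_stats(np.full(5, 0.005))
        assert st_.sd == 0.0 and st_.cv == 0.0


class TestCompareGroups:
    def test_identical_groups_give_p_one(self, rng):
        a = rng.normal(size=30)
        assert compare_groups(a, a.copy()) == pytest.approx(1.0)

    def test_same_distribution_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            if compare_groups(r.normal(size=60), r.normal(size=60)) > 0.05:
                hits += 1
        assert hits >= 90

    def test_separated_means_detected(self, rng):
        a = rng.normal(0.0, 1.0, size=50)
        b = rng.normal(10.0, 1.0, size=50)
        assert compare_groups(a, b) < 1e-6

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(5), np.full(5, 2.0))


class TestScreenOutliers:
    def test_gross_outlier_excluded(self, rng):
        x = rng.normal(size=(40, 30)) * 0.01 + np.linspace(0, 1, 30)[None, :]
        x[13] += 5.0 * rng.normal(size=30)
        report = screen_outliers(make_spectrum_set(x))
        assert "s13" in report.excluded_ids

    def test_clean_cohort_mostly_retained(self, rng):
        x = rng.normal(size=(40, 30))
        report = screen_outliers(make_spectrum_set(x))
        assert len(report.excluded_ids) <= 2
        assert np.all(report.distances >= 0)
        assert set(report.excluded_ids) <= set(report.sample_ids)
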