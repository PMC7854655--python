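"""Conformity index, volume statistics, apparent agreement, Fleiss kappa."""

import numpy as np
import pytest
from conftest import (
    ci_gen_bruteforce,
    cohort_from_masks,
    fleiss_kappa_direct,
    random_cohort,
    small_grid,
)

from contourvar import (
    AgreementSummary,
    StapleResult,
    UndefinedKappaError,
    analysis_region,
    apparent_agreement,
    ci_gen,
    classify_ci,
    classify_kappa,
    overall_kappa,
    performance_summary,
    run_staple,
    summarize_agreement,
    volume_stats,
)


class TestCiGen:
    def test_identical_masks_give_one(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert ci_gen(cohort_from_masks([m] * 4)) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        assert ci_gen(cohort_from_masks([a, b])) == 0.0

    def test_three_observer_worked_example(self):
        # A = {1,2}, B = {2,3}, C = {2} -> sum inter 3, sum union 7
        grid = small_grid(shape=(1, 1, 4))
        A = np.array([[[0, 1, 1, 0]]], bool)
        B = np.array([[[0, 0, 1, 1]]], bool)
        C = np.array([[[0, 0, 1, 0]]], bool)
        val = ci_gen(cohort_from_masks([A, B, C], grid=grid))
        assert val == pytest.approx(3 / 7, abs=1e-15)

    def test_matches_pair_enumeration_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            cohort = random_cohort(rng)
            assert ci_gen(cohort) == pytest.approx(ci_gen_bruteforce(cohort), abs=1e-12)

    def test_invariant_under_observer_permutation_and_refinement(self):
        rng = np.random.default_rng(23)
        cohort = random_cohort(rng, n_observers=4, shape=(6, 6, 6))
        value = ci_gen(cohort)
        perm = [2, 0, 3, 1]
        permuted = cohort_from_masks([cohort.volumes[i].data for i in perm],
                                     grid=cohort.grid)
        assert ci_gen(permuted) == value
        # split every voxel into 8: counts scale by 8 in both sums
        refined = [np.repeat(np.repeat(np.repeat(v.data, 2, 0), 2, 1), 2, 2)
                   for v in cohort.volumes]
        fine = cohort_from_masks(refined, grid=small_grid(shape=(12, 12, 12)))
        assert ci_gen(fine) == value


class TestBands:
    @pytest.mark.parametrize("value,band", [
        (0.45, "weak"), (0.499, "weak"), (0.55, "intermediate"),
        (0.5, "intermediate"), (0.70, "acceptable"), (1.0, "acceptable"),
    ])
    def test_ci_bands(self, value, band):
        assert classify_ci(value) == band

    def test_ci_band_domain(self):
        with pytest.raises(ValueError):
            classify_ci(1.2)

    @pytest.mark.parametrize("value,band", [
        (0.58, "moderate"), (0.54, "moderate"), (0.60, "moderate"),
        (0.66, "substantial"), (0.68, "substantial"), (0.64, "substantial"),
        (-0.05, "poor"), (0.1, "slight"), (0.3, "fair"), (0.95, "almost perfect"),
    ])
    def test_kappa_bands(self, value, band):
        assert classify_kappa(value) == band

    def test_kappa_band_domain(self):
        with pytest.raises(ValueError):
            classify_kappa(1.1)


class TestVolumeStats:
    def test_identical_100_voxel_masks(self):
        m = np.zeros((10, 10, 10), bool)
        m[:5, :5, :4] = True  # 100 voxels at 1 mm^3 = 0.1 cm^3
        stats = volume_stats(cohort_from_masks([m, m, m]))
        assert stats["volume_min"] == stats["volume_max"] == pytest.approx(0.1)
        assert stats["volume_mean"] == pytest.approx(0.1)
        assert stats["volume_sd"] == pytest.approx(0.0, abs=1e-12)
        assert stats["volume_union"] == stats["volume_intersection"] == pytest.approx(0.1)

    def test_two_mask_hand_example(self):
        # {1,2} and {2,3} at 1 cm^3 per voxel
        grid = small_grid(shape=(1, 1, 4), spacing=(10.0, 10.0, 10.0))
        a = np.array([[[0, 1, 1, 0]]], bool)
        b = np.array([[[0, 0, 1, 1]]], bool)
        stats = volume_stats(cohort_from_masks([a, b], grid=grid))
        assert stats["volume_union"] == pytest.approx(3.0)
        assert stats["volume_intersection"] == pytest.approx(1.0)
        assert stats["volume_mean"] == pytest.approx(2.0)
        assert stats["volume_sd"] == pytest.approx(0.0)

    def test_ordering_invariant_on_random_cohorts(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            s = volume_stats(random_cohort(rng))
            assert (s["volume_intersection"] <= s["volume_min"] + 1e-12
                    <= s["volume_mean"] + 1e-12 <= s["volume_max"] + 1e-12
                    <= s["volume_union"] + 1e-12)


class TestApparentAgreement:
    def test_perfect_agreement_is_one(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3, 1:3, 1:3] = True
        cohort = cohort_from_masks([m, m, m])
        region = analysis_region(cohort, 2)
        assert apparent_agreement(cohort, region) == 1.0

    def test_total_disagreement_is_zero(self):
        a = np.ones((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        region = np.ones((2, 2, 2), bool)
        assert apparent_agreement(cohort_from_masks([a, b]), region) == 0.0

    def test_three_observer_single_voxel_pairs(self):
        grid = small_grid(shape=(1, 1, 1))
        one = np.ones((1, 1, 1), bool)
        zero = np.zeros((1, 1, 1), bool)
        cohort = cohort_from_masks([one, one, zero], grid=grid)
        region = np.ones((1, 1, 1), bool)
        assert apparent_agreement(cohort, region) == pytest.approx(1 / 3)


class TestOverallKappa:
    def test_perfect_agreement_both_categories(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3, 1:3, 1:3] = True
        cohort = cohort_from_masks([m, m, m, m])
        res = overall_kappa(cohort, analysis_region(cohort, 2))
        assert res.kappa == pytest.approx(1.0)

    def test_worked_vote_pattern_3_2_1_0(self):
        """3 raters, 4 voxels with vote counts (3,2,1,0): kappa = 1/3."""
        grid = small_grid(shape=(1, 1, 4))
        o1 = np.array([[[1, 1, 1, 0]]], bool)
        o2 = np.array([[[1, 1, 0, 0]]], bool)
        o3 = np.array([[[1, 0, 0, 0]]], bool)
        cohort = cohort_from_masks([o1, o2, o3], grid=grid)
        res = overall_kappa(cohort, np.ones((1, 1, 4), bool))
        assert res.kappa == pytest.approx(1 / 3, abs=1e-12)
        assert res.observed_agreement == pytest.approx(2 / 3)
        assert res.chance_agreement == pytest.approx(0.5)

    def test_matches_statsmodels_on_random_vote_tables(self):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(41)
        for _ in range(20):
            J = int(rng.integers(2, 8))
            N = int(rng.integers(20, 200))
            table = rng.random((J, N)) < rng.uniform(0.2, 0.8)
            if table.all() or not table.any():
                continue
            cohort = cohort_from_masks(
                [row.reshape(1, 1, -1) for row in table],
                grid=small_grid(shape=(1, 1, N)),
            )
            res = overall_kappa(cohort, np.ones((1, 1, N), bool))
            votes = table.sum(axis=0)
            counts = np.stack([votes, J - votes], axis=1)
            expected = sm.fleiss_kappa(counts, method="fleiss")
            assert res.kappa == pytest.approx(expected, abs=1e-10)

    def test_chance_level_votes_give_near_zero_kappa(self):
        rng = np.random.default_rng(43)
        N = 40000
        table = rng.random((5, N)) < 0.5
        cohort = cohort_from_masks([r.reshape(1, 1, -1) for r in table],
                                   grid=small_grid(shape=(1, 1, N)))
        res = overall_kappa(cohort, np.ones((1, 1, N), bool))
        assert abs(res.kappa) < 0.01
        assert res.p_value > 1e-4  # chance agreement is not significant

    def test_single_category_region_is_undefined(self):
        m = np.ones((3, 3, 3), bool)
        cohort = cohort_from_masks([m, m])
        with pytest.raises(UndefinedKappaError):
            overall_kappa(cohort, np.ones((3, 3, 3), bool))

    def test_apparent_agreement_equals_fleiss_observed_term(self):
        rng = np.random.default_rng(47)
        cohort = random_cohort(rng)
        region = analysis_region(cohort, 1)
        res = overall_kappa(cohort, region)
        assert apparent_agreement(cohort, region) == pytest.approx(
            res.observed_agreement, abs=1e-15
        )

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(10):
            cohort = random_cohort(rng)
            region = analysis_region(cohort, 2)
            res = overall_kappa(cohort, region)
            votes = cohort.vote_counts()[region]
            assert res.kappa == pytest.approx(
                fleiss_kappa_direct(votes, len(cohort)), abs=1e-12
            )


class TestPerformanceAndSummary:
    def _result(self, p, q):
        grid = small_grid(shape=(2, 2, 2))
        return StapleResult(
            grid=grid,
            probability_map=np.zeros((2, 2, 2)),
            sensitivities=np.asarray(p, float),
            specificities=np.asarray(q, float),
            prior=0.5,
            region=np.ones((2, 2, 2), bool),
            iterations=1,
            converged=True,
        )

    def test_equal_values_have_zero_sd(self):
        s = performance_summary(self._result([0.9, 0.9, 0.9], [0.8, 0.8, 0.8]))
        assert s["sensitivity_sd"] == 0.0

    def test_hand_arithmetic_example(self):
        s = performance_summary(self._result([0.8, 0.9, 1.0], [0.7, 0.8, 0.9]))
        assert s["sensitivity_mean"] == pytest.approx(0.9)
        assert s["sensitivity_sd"] == pytest.approx(0.1)
        assert s["specificity_mean"] == pytest.approx(0.8)

    def test_summary_satisfies_ordering_invariants(self):
        rng = np.random.default_rng(59)
        truth = np.zeros((12, 12, 12), bool)
        truth[3:9, 3:9, 3:9] = True
        for _ in range(5):
            masks = []
            for _ in range(5):
                u = rng.random(truth.shape)
                masks.append(np.where(truth, u < 0.9, u < 0.06))
            cohort = cohort_from_masks(masks)
            res = run_staple(cohort)
            summary = summarize_agreement(cohort, res)
            assert isinstance(summary, AgreementSummary)
            assert 0 <= summary.apparent_agreement <= 1
            assert summary.n_observers == 5
            d = summary.to_dict()
            assert d["region_voxels"] == int(res.region.sum())
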