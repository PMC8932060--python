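"""Validation metrics: HU error, overlap, gamma, DVH, statistics."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from pelvisynth.validation import (
    DVHCurve,
    GammaCriteria,
    RegionSpec,
    dice,
    dvh_cumulative,
    dvh_metric,
    gamma_3d,
    gamma_3d_bruteforce,
    mean_absolute_error,
    mean_error,
    paired_signed_rank_test,
    pct_dose_difference,
    restrict_region,
    volume_difference_pct,
)
from pelvisynth.volumes import DoseGrid, Modality

from conftest import make_mask, make_volume


class TestRestrictRegion:
    def test_zero_exclusion_is_identity(self):
        mask = make_mask(np.ones((4, 4, 10)), spacing=(2, 2, 2))
        out = restrict_region(RegionSpec(mask, 0.0), mask)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_full_exclusion_raises(self):
        # 60 mm-long extent, 30 mm stripped from each end -> nothing left
        mask = make_mask(np.ones((4, 4, 30)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="empties"):
            restrict_region(RegionSpec(mask, 30.0), mask)

    def test_slice_arithmetic(self):
        # 100 mm extent at 2 mm slices, 30 mm exclusion -> 20 central slices
        mask = make_mask(np.ones((4, 4, 50)), spacing=(2, 2, 2))
        out = restrict_region(RegionSpec(mask, 30.0), mask)
        kept = np.where(out.voxels[0, 0])[0]
        assert len(kept) == 20
        assert kept[0] == 15 and kept[-1] == 34


class TestHUErrors:
    def _region(self, shape=(6, 6, 6)):
        return RegionSpec(make_mask(np.ones(shape)), 0.0)

    def test_identical_images_zero(self, rng):
        a = make_volume(rng.normal(size=(6, 6, 6)))
        region = self._region()
        assert mean_error(a, a, region) == 0.0
        assert mean_absolute_error(a, a, region) == 0.0

    def test_constant_offset(self, rng):
        a = make_volume(rng.normal(size=(6, 6, 6)))
        b = make_volume(a.voxels + 10.0)
        region = self._region()
        assert mean_error(b, a, region) == pytest.approx(10.0)
        assert mean_absolute_error(b, a, region) == pytest.approx(10.0)

    def test_balanced_errors_cancel_in_me_not_mae(self):
        ref = make_volume(np.zeros((6, 6, 6)))
        ev = np.zeros((6, 6, 6))
        ev[:3] = 10.0
        ev[3:] = -10.0
        region = self._region()
        assert mean_error(make_volume(ev), ref, region) == pytest.approx(0.0)
        assert mean_absolute_error(make_volume(ev), ref, region) == pytest.approx(10.0)

    def test_difference_inside_excluded_margin_ignored(self):
        shape = (4, 4, 50)
        ref = make_volume(np.zeros(shape), spacing=(2, 2, 2))
        ev = np.zeros(shape)
        ev[:, :, :10] = 500.0  # entirely within the 30 mm margin
        region = RegionSpec(make_mask(np.ones(shape), spacing=(2, 2, 2)), 30.0)
        assert mean_error(make_volume(ev, spacing=(2, 2, 2)), ref, region) == 0.0

    def test_mae_dominates_me_randomized(self, rng):
        region = self._region()
        for _ in range(20):
            a = make_volume(rng.normal(size=(6, 6, 6)))
            b = make_volume(rng.normal(size=(6, 6, 6)))
            assert (mean_absolute_error(a, b, region)
                    >= abs(mean_error(a, b, region)) - 1e-12)


class TestDiceAndVolume:
    def test_self_dice_is_one(self):
        m = make_mask(np.ones((5, 5, 5)))
        assert dice(m, m) == 1.0

    def test_disjoint_dice_zero(self):
        a = np.zeros((6, 6, 6)); a[:3] = 1
        b = np.zeros((6, 6, 6)); b[3:] = 1
        assert dice(make_mask(a), make_mask(b)) == 0.0

    def test_half_overlapping_cubes(self):
        # two 10x10x10 cubes overlapping in a 5x10x10 slab -> 2*500/2000
        a = np.zeros((15, 10, 10)); a[:10] = 1
        b = np.zeros((15, 10, 10)); b[5:] = 1
        assert dice(make_mask(a), make_mask(b)) == pytest.approx(0.5)

    def test_dice_symmetric(self, rng):
        a = make_mask(rng.integers(0, 2, size=(6, 6, 6)))
        b = make_mask(rng.integers(0, 2, size=(6, 6, 6)))
        assert dice(a, b) == dice(b, a)

    def test_volume_difference_pct(self):
        ref = np.zeros((10, 10, 10)); ref[:, :, :5] = 1  # 500 voxels
        ev = ref.copy(); ev[0, :, 0] = 0  # 490 voxels
        out = volume_difference_pct(make_mask(ev), make_mask(ref))
        assert out == pytest.approx(-2.0)

    def test_volume_pct_scale_invariant(self):
        ref = np.zeros((10, 10, 10)); ref[:5] = 1
        ev = np.zeros((10, 10, 10)); ev[:4] = 1
        d1 = volume_difference_pct(make_mask(ev, spacing=(1, 1, 1)),
                                   make_mask(ref, spacing=(1, 1, 1)))
        d2 = volume_difference_pct(make_mask(ev, spacing=(2, 2, 2)),
                                   make_mask(ref, spacing=(2, 2, 2)))
        assert d1 == pytest.approx(d2)


def _smooth_dose(rng, shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0), base=None):
    arr = rng.uniform(0, 1, size=shape)
    arr = gaussian_filter(arr, sigma=3.0)
    arr = 50.0 * (arr - arr.min()) / (arr.max() - arr.min())
    if base is not None:
        arr = base + arr * 0.02
    img = make_volume(arr, spacing=spacing, modality=Modality.DOSE)
    return DoseGrid(image=img)


def _full_body(shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0)):
    return make_mask(np.ones(shape), spacing=spacing)


#: erosion small enough to leave an evaluable core on the 24^3 test grids
ORACLE_CRITERIA = GammaCriteria(dose_tol_pct=2.0, dta_mm=2.0,
                                low_threshold_pct=10.0, erosion_mm=6.0)


class TestGammaAnalytic:
    def _uniform_pair(self, factor, shape=(20, 20, 20)):
        ref = make_volume(np.full(shape, 50.0), spacing=(2, 2, 2),
                          modality=Modality.DOSE)
        ev = make_volume(np.full(shape, 50.0 * factor), spacing=(2, 2, 2),
                         modality=Modality.DOSE)
        body = _full_body(shape, (2, 2, 2))
        return DoseGrid(image=ref), DoseGrid(image=ev), body

    def test_identical_grids_pass_100_mean_0(self, rng):
        d = _smooth_dose(rng)
        res = gamma_3d(d, d, _full_body(), ORACLE_CRITERIA)
        assert res.pass_rate_pct == 100.0
        assert res.mean_gamma == 0.0

    def test_uniform_3pct_off_fails_everywhere(self):
        ref, ev, body = self._uniform_pair(1.03)
        res = gamma_3d(ref, ev, body, GammaCriteria(2.0, 2.0, erosion_mm=6.0))
        assert res.pass_rate_pct == 0.0
        evaluated = res.gamma_map.voxels[res.gamma_map.voxels >= 0]
        np.testing.assert_allclose(evaluated, 1.5, atol=1e-9)

    def test_uniform_2pct_off_is_exactly_on_boundary(self):
        ref, ev, body = self._uniform_pair(1.02)
        res = gamma_3d(ref, ev, body, GammaCriteria(2.0, 2.0, erosion_mm=6.0))
        assert res.pass_rate_pct == 100.0
        evaluated = res.gamma_map.voxels[res.gamma_map.voxels >= 0]
        np.testing.assert_allclose(evaluated, 1.0, atol=1e-9)

    def test_unevaluated_voxels_carry_sentinel(self, rng):
        d = _smooth_dose(rng)
        res = gamma_3d(d, d, _full_body(), ORACLE_CRITERIA)
        assert np.any(res.gamma_map.voxels == -1.0)
        assert res.n_evaluated == int((res.gamma_map.voxels >= 0).sum())

    def test_empty_domain_raises(self, rng):
        d = _smooth_dose(rng)
        with pytest.raises(ValueError, match="empty gamma"):
            gamma_3d(d, d, _full_body(),
                     GammaCriteria(2.0, 2.0, erosion_mm=100.0))


class TestGammaOracle:
    def test_matches_bruteforce_on_random_smooth_pairs(self, rng):
        for trial in range(3):
            ref = _smooth_dose(rng)
            ev = _smooth_dose(rng, base=ref.image.voxels)
            res = gamma_3d(ref, ev, _full_body(), ORACLE_CRITERIA)
            domain = res.gamma_map.voxels >= 0
            vox = np.argwhere(domain)
            sample = vox[rng.choice(len(vox), size=50, replace=False)]
            expected = gamma_3d_bruteforce(ref, ev, _full_body(),
                                           ORACLE_CRITERIA, sample)
            got = res.gamma_map.voxels[tuple(sample.T)]
            np.testing.assert_allclose(got, expected, atol=1e-6)


class TestGammaMonotonicity:
    def test_tighter_criteria_never_raise_pass_rate(self, rng):
        for _ in range(3):
            ref = _smooth_dose(rng)
            ev = _smooth_dose(rng, base=ref.image.voxels)
            rates = []
            for tol, dta in [(1.0, 1.0), (2.0, 2.0), (3.0, 2.0)]:
                crit = GammaCriteria(tol, dta, erosion_mm=6.0)
                rates.append(gamma_3d(ref, ev, _full_body(), crit).pass_rate_pct)
            assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9

    def test_erosion_never_increases_evaluated_count(self, rng):
        ref = _smooth_dose(rng)
        ev = _smooth_dose(rng, base=ref.image.voxels)
        counts = []
        for erosion in [2.0, 6.0, 10.0]:
            crit = GammaCriteria(2.0, 2.0, erosion_mm=erosion)
            counts.append(gamma_3d(ref, ev, _full_body(), crit).n_evaluated)
        assert counts[0] >= counts[1] >= counts[2]


class TestDVH:
    def _uniform_dose(self, value, shape=(8, 8, 8)):
        img = make_volume(np.full(shape, value), modality=Modality.DOSE)
        return DoseGrid(image=img)

    def test_uniform_dose_step_curve(self):
        dose = self._uniform_dose(20.0)
        roi = make_mask(np.ones((8, 8, 8)))
        curve = dvh_cumulative(dose, roi, bin_width_gy=0.5)
        below = curve.dose_bins <= 20.0
        np.testing.assert_allclose(curve.cum_volume_pct[below], 100.0)
        np.testing.assert_allclose(curve.cum_volume_pct[~below], 0.0)

    def test_curve_non_increasing(self, rng):
        arr = np.abs(gaussian_filter(rng.normal(size=(12, 12, 12)), 2)) * 50
        dose = DoseGrid(image=make_volume(arr, modality=Modality.DOSE))
        roi = make_mask(np.ones((12, 12, 12)))
        curve = dvh_cumulative(dose, roi)
        assert np.all(np.diff(curve.cum_volume_pct) <= 1e-12)

    def test_linear_gradient_analytic(self):
        # dose rising 0 -> 60 Gy along one axis over equal-volume voxels
        n = 60
        arr = np.tile(np.linspace(0, 60, n)[None, None, :], (4, 4, 1))
        dose = DoseGrid(image=make_volume(arr, modality=Modality.DOSE))
        roi = make_mask(np.ones((4, 4, n)))
        curve = dvh_cumulative(dose, roi, bin_width_gy=0.5)
        # analytic: fraction >= d is (60 - d)/60
        for d in [10.0, 30.0, 45.0]:
            expected = 100.0 * (60.0 - d) / 60.0
            assert dvh_metric(curve, f"V{d}") == pytest.approx(expected, abs=2.0)

    def test_uniform_dose_metrics_coincide(self):
        dose = self._uniform_dose(20.0)
        roi = make_mask(np.ones((8, 8, 8)))
        curve = dvh_cumulative(dose, roi, 0.1)
        assert dvh_metric(curve, "D98") == pytest.approx(20.0, abs=0.1)
        assert dvh_metric(curve, "D2") == pytest.approx(20.0, abs=0.1)
        assert dvh_metric(curve, "Dmean", dose=dose, roi=roi) == pytest.approx(20.0)

    def test_gradient_median_and_mean(self):
        n = 120
        arr = np.tile(np.linspace(0, 60, n)[None, None, :], (2, 2, 1))
        dose = DoseGrid(image=make_volume(arr, modality=Modality.DOSE))
        roi = make_mask(np.ones((2, 2, n)))
        curve = dvh_cumulative(dose, roi, bin_width_gy=0.5)
        assert dvh_metric(curve, "Dmean", dose=dose, roi=roi) == pytest.approx(30.0)
        assert dvh_metric(curve, "D50") == pytest.approx(30.0, abs=0.5)


class TestPctDoseDifference:
    def test_paper_formula_arithmetic(self):
        assert pct_dose_difference(49.8, 50.0) == pytest.approx(-0.4)

    def test_equal_doses_zero(self):
        assert pct_dose_difference(50.0, 50.0) == 0.0

    def test_antisymmetry_identity(self, rng):
        for _ in range(10):
            a, b = rng.uniform(1, 100, size=2)
            # -((b-a)/a)*(a/b)*100 = (a-b)/b*100
            assert pct_dose_difference(a, b) == pytest.approx(
                -pct_dose_difference(b, a) * (a / b))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pct_dose_difference(1.0, 0.0)


def signed_rank_p_enumeration(diffs):
    """Exhaustive sign-flip enumeration oracle for the exact two-sided
    signed-rank p-value (n <= 12)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.asarray(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_symmetric_sample_p_one(self):
        assert paired_signed_rank_test([-3, -1, 1, 3]) == pytest.approx(1.0)

    def test_one_sided_extreme_n6(self):
        # all positive: the two most extreme of 2^6 assignments
        assert paired_signed_rank_test([1, 2, 3, 4, 5, 6]) == pytest.approx(2 / 64)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            paired_signed_rank_test([0.0, 0.0])

    def test_zeros_dropped(self):
        p_with = paired_signed_rank_test([0.0, 1, 2, 3, 4, 5, 6, 0.0])
        p_without = paired_signed_rank_test([1, 2, 3, 4, 5, 6])
        assert p_with == pytest.approx(p_without)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = np.round(rng.normal(scale=3, size=n), 1)
        d = d[d != 0]
        if len(d) == 0:
            return
        assert paired_signed_rank_test(d) == pytest.approx(
            signed_rank_p_enumeration(d))

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon

        d = [1.3, -0.7, 2.1, 3.3, -4.2, 0.6, 1.9, -2.8]
        p_ours = paired_signed_rank_test(d)
        p_scipy = wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p_ours == pytest.approx(p_scipy)

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(loc=0.3, size=40)
        p = paired_signed_rank_test(d)
        from scipy.stats import wilcoxon

        p_scipy = wilcoxon(d, alternative="two-sided", method="approx",
                           correction=False).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)


class TestDVHCurveInvariants:
    def test_rejects_increasing_volume(self):
        with pytest.raises(ValueError):
            DVHCurve(dose_bins=np.array([0.0, 1.0]),
                     cum_volume_pct=np.array([50.0, 80.0]))

    def test_rejects_unsorted_bins(self):
        with pytest.raises(ValueError):
            DVHCurve(dose_bins=np.array([1.0, 0.5]),
                     cum_volume_pct=np.array([100.0, 50.0]))
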