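"""Phantom generator: determinism, ground-truth conservation, degradation."""

import numpy as np
import pytest

from cacforge import scoring
from cacforge.phantom import (
    GeometryConfig,
    degrade_to_ctac,
    generate_case,
    generate_cohort,
    lesion_table,
    true_scores,
)
from cacforge.volume import CTVolume, Modality

from .oracles import pseudomass_oracle

#: reduced grid for tests that generate many cases
SMALL_GEO = GeometryConfig(
    csct_shape=(16, 96, 96),
    heart_semiaxes_mm=(13.0, 12.0, 15.0),
    lesion_extent_mm=(1.5, 4.0),
)


@pytest.fixture(scope="module")
def case():
    return generate_case(seed=7, n_lesions=3)


class TestGenerateCase:
    def test_zero_lesion_case_is_calcium_free(self):
        case = generate_case(seed=7, n_lesions=0, geometry=SMALL_GEO)
        assert not case.calcium_mask_csct.any()
        assert case.lesion_truth == []
        assert true_scores(case).pseudomass == 0.0
        assert true_scores(case).agatston == 0.0

    def test_seeded_determinism_bit_identical(self):
        a = generate_case(seed=7, n_lesions=3, geometry=SMALL_GEO)
        b = generate_case(seed=7, n_lesions=3, geometry=SMALL_GEO)
        np.testing.assert_array_equal(a.csct.voxels, b.csct.voxels)
        np.testing.assert_array_equal(a.ctac_rest.voxels, b.ctac_rest.voxels)
        np.testing.assert_array_equal(a.ctac_stress.voxels, b.ctac_stress.voxels)
        np.testing.assert_array_equal(a.calcium_mask_csct, b.calcium_mask_csct)

    def test_acquisition_grids(self, case):
        assert case.csct.spacing == pytest.approx((0.4, 0.4, 2.5))
        assert case.ctac_rest.spacing == pytest.approx((1.17, 1.17, 5.0))
        assert case.ctac_stress.spacing == pytest.approx((1.17, 1.17, 5.0))

    def test_calcium_only_inside_heart(self, case):
        assert case.heart_mask_csct[case.calcium_mask_csct].all()

    def test_lesion_truth_invariants(self, case):
        assert len(case.lesion_truth) == 3
        for truth in case.lesion_truth:
            assert truth.peak_hu >= 150
            assert truth.true_pseudomass > 0

    def test_rest_and_stress_differ_only_by_noise(self, case):
        # same underlying anatomy: identical grids, different noise draws
        assert case.ctac_rest.shape == case.ctac_stress.shape
        assert not np.array_equal(case.ctac_rest.voxels, case.ctac_stress.voxels)
        diff = case.ctac_rest.voxels.astype(float) - case.ctac_stress.voxels
        assert abs(diff.mean()) < 5.0  # zero-mean noise difference

    def test_negative_lesion_count_rejected(self):
        with pytest.raises(ValueError):
            generate_case(seed=1, n_lesions=-1)

    def test_low_peak_hu_rejected(self):
        with pytest.raises(ValueError):
            generate_case(seed=1, n_lesions=1, hu_range=(100, 300))

    def test_true_scores_deterministic(self, case):
        s1 = true_scores(case)
        s2 = true_scores(case)
        assert s1.pseudomass == s2.pseudomass
        assert s1.agatston == s2.agatston


class TestGroundTruthConservation:
    def test_pseudomass_matches_brute_force_voxel_sum(self):
        case = generate_case(seed=21, n_lesions=2, geometry=SMALL_GEO)
        voxvol = case.csct.voxel_volume_mm3
        expected = float(case.inserted_hu_csct.sum()) * voxvol
        assert true_scores(case).pseudomass == pytest.approx(expected)
        # explicit loop oracle over the inserted field
        oracle = pseudomass_oracle(
            case.inserted_hu_csct.tolist(),
            case.calcium_mask_csct.tolist(),
            case.csct.spacing,
        )
        assert true_scores(case).pseudomass == pytest.approx(oracle)

    def test_per_lesion_masses_sum_to_total(self):
        case = generate_case(seed=22, n_lesions=3, geometry=SMALL_GEO)
        assert sum(t.true_pseudomass for t in case.lesion_truth) == pytest.approx(
            true_scores(case).pseudomass
        )

    def test_hand_computed_three_voxel_lesion(self):
        # inserted HU 200/300/400 at voxel volume 1.5 mm^3 -> 900 * 1.5 = 1350
        inserted = np.zeros((1, 4, 4), dtype=int)
        inserted[0, 1, 1:4] = [200, 300, 400]
        voxvol = 1.5
        assert float(inserted.sum()) * voxvol == pytest.approx(1350.0)


class TestDegradation:
    def make_volume(self):
        vox = np.full((8, 32, 32), 40.0)
        vox[3:5, 14:18, 14:18] = 400.0
        return CTVolume(vox, spacing=(1.0, 1.0, 2.5))

    def test_identity_degradation(self):
        vol = self.make_volume()
        out = degrade_to_ctac(vol, 0.0, 0.0, 2.5, seed=0)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_slice_averaging_lowers_single_voxel_peak(self):
        vox = np.full((8, 16, 16), 0.0)
        vox[4, 8, 8] = 400.0
        vol = CTVolume(vox, spacing=(1.0, 1.0, 2.5))
        out = degrade_to_ctac(vol, 0.0, 0.0, 5.0, seed=0)
        assert out.voxels.max() < 400

    def test_finer_target_thickness_rejected(self):
        with pytest.raises(ValueError):
            degrade_to_ctac(self.make_volume(), 1.0, 10.0, 1.0, seed=0)

    def test_blur_monotonically_lowers_lesion_peak(self):
        vol = self.make_volume()
        peaks = [
            degrade_to_ctac(vol, (s, s, s), 0.0, 5.0, seed=0).voxels.max()
            for s in [0.0, 0.5, 1.0, 2.0, 3.0, 4.0]
        ]
        assert all(p1 >= p2 for p1, p2 in zip(peaks, peaks[1:]))

    def test_blur_sweep_crosses_detection_threshold(self):
        # a 2 mm lesion at 300 HU falls below 130 HU beyond some sigma*
        vox = np.full((8, 32, 32), 40.0)
        vox[4, 15:17, 15:17] = 300.0
        vol = CTVolume(vox, spacing=(1.0, 1.0, 2.5))
        sigmas = np.linspace(0.0, 4.0, 17)
        peaks = [
            degrade_to_ctac(vol, (s, s, s), 0.0, 5.0, seed=0).voxels.max()
            for s in sigmas
        ]
        assert peaks[0] >= 130  # visible without motion blur
        below = [s for s, p in zip(sigmas, peaks) if p < 130]
        assert below, "no blur level pushed the lesion below 130 HU"
        sigma_star = min(below)
        # all stronger blurs stay below threshold (monotone crossing)
        assert all(p < 130 for s, p in zip(sigmas, peaks) if s >= sigma_star)


class TestCohort:
    def test_zero_calcium_fraction_matches_lesion_rate_prior(self):
        # n_lesions ~ Uniform{0..5}: zero-calcium probability 1/6
        cases = generate_cohort(100, seed=5, lesion_rate=(0, 5), geometry=SMALL_GEO)
        frac = np.mean([len(c.lesion_truth) == 0 for c in cases])
        # binomial sd ~ 0.037 at n=100; allow ~3.5 sd
        assert abs(frac - 1 / 6) < 0.13

    def test_lesion_table_columns_and_rows(self):
        cases = generate_cohort(4, seed=6, lesion_rate=(1, 2), geometry=SMALL_GEO)
        table = lesion_table(cases)
        assert set(table.columns) >= {
            "case_id", "lesion_id", "peak_hu", "true_pseudomass", "true_agatston",
        }
        assert len(table) == sum(len(c.lesion_truth) for c in cases)

    def test_modalities_assigned(self):
        case = generate_case(seed=30, n_lesions=1, geometry=SMALL_GEO)
        assert case.csct.modality == Modality.CSCT
        assert case.ctac_rest.modality == Modality.CTAC_REST
        assert case.ctac_stress.modality == Modality.CTAC_STRESS
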