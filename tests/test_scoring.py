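"""Lesion extraction, pseudomass, Agatston scoring, risk categories, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cacforge import scoring
from cacforge.scoring import (
    REST_PARAMS,
    STRESS_PARAMS,
    CalibrationParams,
    agatston,
    agatston_from_lesions,
    calibrate,
    categorize_agatston,
    categorize_auto,
    extract_lesions_from_map,
    extract_lesions_threshold,
    pseudomass,
    risk_category,
    vis_auto,
)
from cacforge.volume import CTVolume

from .oracles import agatston_oracle


def make_volume(voxels, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(voxels), spacing=spacing)


def full_heart(vol):
    return np.ones(vol.shape, dtype=bool)


class TestLesionExtraction:
    def test_all_below_threshold_gives_empty_set(self):
        vol = make_volume(np.full((3, 8, 8), 100))
        assert len(extract_lesions_threshold(vol, full_heart(vol))) == 0

    def test_single_blob_area_and_max_hu(self):
        vox = np.zeros((1, 8, 8))
        vox[0, 2:4, 2:4] = 260  # 4 pixels of 1 mm^2
        vol = make_volume(vox)
        lesions = extract_lesions_threshold(vol, full_heart(vol))
        assert len(lesions) == 1
        lesion = lesions.lesions[0]
        assert lesion.slice_areas_mm2[0] == pytest.approx(4.0)
        assert lesion.slice_max_hu[0] == 260

    def test_separated_blobs_are_distinct_lesions(self):
        vox = np.zeros((1, 10, 10))
        vox[0, 1:3, 1:3] = 200
        vox[0, 6:8, 6:8] = 200  # > 1 voxel gap
        vol = make_volume(vox)
        assert len(extract_lesions_threshold(vol, full_heart(vol))) == 2

    def test_mask_excludes_outside_heart(self):
        vox = np.full((1, 6, 6), 300.0)
        vol = make_volume(vox)
        heart = np.zeros(vol.shape, dtype=bool)
        heart[0, :3, :] = True
        lesions = extract_lesions_threshold(vol, heart)
        total_voxels = sum(l.n_voxels for l in lesions)
        assert total_voxels == 18

    def test_misaligned_mask_raises(self):
        vol = make_volume(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            extract_lesions_threshold(vol, np.ones((2, 5, 5), dtype=bool))

    def test_map_route_keeps_sub_threshold_values(self):
        # map marks 3 voxels whose original HU are 90/150/200: all retained
        vox = np.zeros((1, 6, 6))
        vox[0, 2, 1:4] = [90, 150, 200]
        vol = make_volume(vox)
        cac_map = np.zeros(vol.shape)
        cac_map[0, 2, 1:4] = 100.0
        lesions = extract_lesions_from_map(cac_map, vol, full_heart(vol), map_floor_hu=30)
        assert len(lesions) == 1
        z, y, x = lesions.lesions[0].voxels.T
        assert sorted(vol.voxels[z, y, x].tolist()) == [90, 150, 200]

    def test_empty_map_gives_empty_set(self):
        vol = make_volume(np.full((2, 6, 6), 500))
        lesions = extract_lesions_from_map(np.zeros(vol.shape), vol, full_heart(vol), 30)
        assert len(lesions) == 0

    def test_map_grid_mismatch_raises(self):
        vol = make_volume(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            extract_lesions_from_map(np.zeros((2, 5, 5)), vol, full_heart(vol), 30)


class TestPseudomass:
    def test_empty_lesions_zero(self):
        vol = make_volume(np.zeros((2, 4, 4)))
        assert pseudomass(extract_lesions_threshold(vol, full_heart(vol)), vol) == 0.0

    def test_hand_computed_sum(self):
        # voxels 200/300/400 HU at voxel volume 1.5 mm^3 -> 900 * 1.5 = 1350
        vox = np.zeros((1, 6, 6))
        vox[0, 2, 1:4] = [200, 300, 400]
        vol = make_volume(vox, spacing=(1.0, 1.0, 1.5))
        lesions = extract_lesions_threshold(vol, full_heart(vol))
        assert pseudomass(lesions, vol) == pytest.approx(1350.0)

    def test_linear_in_voxel_volume(self):
        vox = np.zeros((1, 6, 6))
        vox[0, 2, 1:4] = [200, 300, 400]
        v1 = make_volume(vox, spacing=(1.0, 1.0, 1.5))
        v2 = make_volume(vox, spacing=(1.0, 1.0, 3.0))
        m1 = pseudomass(extract_lesions_threshold(v1, full_heart(v1)), v1)
        m2 = pseudomass(extract_lesions_threshold(v2, full_heart(v2)), v2)
        assert m2 == pytest.approx(2 * m1)

    def test_additive_over_disjoint_lesions(self):
        vox = np.zeros((1, 12, 12))
        vox[0, 1:3, 1:3] = 300
        vox[0, 8:10, 8:10] = 200
        vol = make_volume(vox)
        both = pseudomass(extract_lesions_threshold(vol, full_heart(vol)), vol)
        assert both == pytest.approx(4 * 300 + 4 * 200)

    def test_negative_hu_clipped_in_map_route(self):
        vox = np.full((1, 4, 4), -50.0)
        vol = make_volume(vox)
        cac_map = np.full(vol.shape, 100.0)
        lesions = extract_lesions_from_map(cac_map, vol, full_heart(vol), 30)
        assert pseudomass(lesions, vol) == 0.0


class TestAgatston:
    def test_nothing_above_threshold_scores_zero(self):
        vol = make_volume(np.full((3, 8, 8), 120))
        assert agatston(vol, full_heart(vol)) == 0.0

    @pytest.mark.parametrize("hu,expected", [(260, 8.0), (450, 16.0), (150, 4.0), (350, 12.0)])
    def test_weight_table_on_four_pixel_blob(self, hu, expected):
        vox = np.zeros((1, 8, 8))
        vox[0, 2:4, 2:4] = hu
        vol = make_volume(vox)
        assert agatston(vol, full_heart(vol)) == pytest.approx(expected)

    def test_min_area_rule_drops_single_pixel_speck(self):
        vox = np.zeros((1, 8, 8))
        vox[0, 3, 3] = 500
        vol = make_volume(vox, spacing=(0.5, 0.5, 1.0))  # 0.25 mm^2 < 1 mm^2
        assert agatston(vol, full_heart(vol)) == 0.0

    def test_matches_brute_force_oracle_on_random_phantoms(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            shape = (4, 14, 14)
            vox = rng.integers(-100, 250, size=shape).astype(float)
            # sprinkle a few bright seeds so components exist
            for _ in range(rng.integers(0, 6)):
                z, y, x = rng.integers(0, shape[0]), rng.integers(1, 13), rng.integers(1, 13)
                vox[z, max(0, y - 1) : y + 1, max(0, x - 1) : x + 1] = rng.integers(130, 900)
            heart = rng.random(shape) > 0.1
            spacing = (float(rng.choice([0.5, 1.0, 1.5])),) * 2 + (2.0,)
            vol = CTVolume(vox, spacing=spacing)
            expected = agatston_oracle(vol.voxels.tolist(), spacing, heart.tolist())
            assert agatston(vol, heart) == pytest.approx(expected, abs=1e-9)

    def test_threshold_and_map_routes_agree_on_ideal_map(self):
        # CAC-map defined as HU * [HU >= 130] makes both routes identical
        rng = np.random.default_rng(12)
        vox = rng.integers(-50, 200, (4, 16, 16)).astype(float)
        vox[1, 4:7, 4:7] = 300
        vol = make_volume(vox)
        heart = full_heart(vol)
        ideal_map = np.where(vol.voxels >= 130, vol.voxels, 0).astype(float)
        thr = extract_lesions_threshold(vol, heart, 130)
        mapped = extract_lesions_from_map(ideal_map, vol, heart, map_floor_hu=130)
        assert pseudomass(thr, vol) == pytest.approx(pseudomass(mapped, vol))
        assert agatston_from_lesions(thr) == pytest.approx(agatston_from_lesions(mapped))


class TestRiskCategories:
    @pytest.mark.parametrize(
        "score,cat",
        [(0, 1), (0.5, 2), (1, 2), (5, 2), (10, 2), (10.5, 3), (11, 3), (100, 3),
         (101, 4), (400, 4), (400.5, 5), (401, 5), (10_000, 5)],
    )
    def test_agatston_category_boundaries(self, score, cat):
        assert categorize_agatston(score).category == cat

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            categorize_agatston(-1)

    def test_vis_auto_zero_mass_is_zero(self):
        assert vis_auto(0.0, REST_PARAMS) == 0.0
        assert vis_auto(0.0, STRESS_PARAMS) == 0.0

    def test_vis_auto_hand_values(self):
        # rest: gamma*mass = 9 -> log_9 = 1 -> 3.1 - 1.6 = 1.5
        assert vis_auto(9.0 / 1.1, REST_PARAMS) == pytest.approx(1.5, abs=1e-12)
        # stress: mass 81 -> log_9 = 2 -> 7.0 - 1.5 = 5.5
        assert vis_auto(81.0, STRESS_PARAMS) == pytest.approx(5.5, abs=1e-12)

    def test_vis_auto_strictly_increasing(self):
        masses = np.logspace(-2, 6, 50)
        vals = [vis_auto(m, REST_PARAMS) for m in masses]
        assert np.all(np.diff(vals) > 0)

    def test_categorize_auto_zero_mass_forced_to_I(self):
        assert categorize_auto(0.0, mass=0.0).category == 1
        assert categorize_auto(3.7, mass=0.0).category == 1

    @pytest.mark.parametrize("vis,cat", [(1.5, 2), (1.49, 1), (2.5, 3), (7.2, 5), (-3.0, 1)])
    def test_categorize_auto_round_half_up_and_clamp(self, vis, cat):
        assert categorize_auto(vis, mass=10.0).category == cat

    def test_categorize_auto_monotone_in_mass(self):
        cats = [risk_category(m, REST_PARAMS).category for m in np.logspace(-1, 7, 60)]
        assert np.all(np.diff(cats) >= 0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CalibrationParams(alpha=1, beta=1.0, gamma=1, delta=0)
        with pytest.raises(ValueError):
            CalibrationParams(alpha=1, beta=9, gamma=0.0, delta=0)


class TestCalibration:
    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(0)
        masses = np.exp(rng.uniform(0, 9, size=16))
        cats = 3.1 * np.log(masses) / np.log(9.0) - 1.6
        params, rss = calibrate(masses, cats, beta_fixed=9.0, gamma_fixed=1.0)
        assert params.alpha == pytest.approx(3.1, abs=1e-9)
        assert params.delta == pytest.approx(1.6, abs=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-15)

    def test_two_points_interpolated_exactly(self):
        params, rss = calibrate([9.0, 81.0], [2.0, 5.0])
        assert rss == pytest.approx(0.0, abs=1e-18)
        x = np.log(9.0) / np.log(9.0)
        assert params.alpha * x - params.delta == pytest.approx(2.0)

    def test_noisy_recovery_within_half_unit(self):
        # sd 0.25 noise on categories, n=16: alpha within +/-0.5 in >=95% of runs
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            masses = np.exp(rng.uniform(0, 9, size=16))
            cats = 3.1 * np.log(masses) / np.log(9.0) - 1.6 + rng.normal(0, 0.25, 16)
            params, _ = calibrate(masses, cats)
            hits += abs(params.alpha - 3.1) <= 0.5
        assert hits / n_rep >= 0.95

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError):
            calibrate([5.0, 5.0, 5.0], [2, 3, 4])

    def test_nonpositive_mass_raises(self):
        with pytest.raises(ValueError):
            calibrate([0.0, 10.0], [2, 3])


@given(
    hu=st.lists(st.integers(min_value=131, max_value=3000), min_size=1, max_size=20),
    voxvol=st.floats(min_value=0.1, max_value=10.0, allow_nan=False),
)
@settings(max_examples=50, deadline=None)
def test_pseudomass_scales_linearly_with_voxel_volume(hu, voxvol):
    """Pseudomass of a single-slice lesion equals sum(HU) * voxel volume."""
    n = len(hu)
    vox = np.zeros((1, 1, n + 2))
    vox[0, 0, 1 : n + 1] = hu
    vol = CTVolume(vox, spacing=(1.0, 1.0, voxvol))
    lesions = extract_lesions_threshold(vol, np.ones(vol.shape, bool), min_area_mm2=0.0)
    assert pseudomass(lesions, vol) == pytest.approx(sum(hu) * voxvol, rel=1e-9)
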