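import numpy as np
import pytest

from maizestand import (PlantDetector, analyze_image, binarize, compute_exg,
                        detect_plants, extract_objects, filter_objects,
                        merge_fragments)
from maizestand.segment import PlantObject, objects_to_mask


def rgb(r, g, b):
    return np.array([[[r, g, b]]], dtype=np.uint8)


class TestExG:
    @pytest.mark.parametrize("pix,expected", [
        ((100, 100, 100), 0.0),       # grey
        ((0, 255, 0), 2.0),           # pure green, maximum
        ((50, 150, 100), 0.5),        # (300-50-100)/300
        ((0, 0, 0), 0.0),             # zero-sum maps to 0
    ])
    def test_pointwise_values(self, pix, expected):
        assert compute_exg(rgb(*pix))[0, 0] == pytest.approx(expected)

    def test_range_bounds(self):
        img = np.random.default_rng(0).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        exg = compute_exg(img)
        assert exg.min() >= -1.0 and exg.max() <= 2.0

    def test_per_band_max_normalization_cancels_common_scale(self):
        img = np.random.default_rng(1).integers(10, 120, (16, 16, 3), dtype=np.uint8)
        scaled = (img.astype(np.uint16) * 2).astype(np.uint8)  # still < 256
        a = compute_exg(img, normalization="per_band_image_max")
        b = compute_exg(scaled, normalization="per_band_image_max")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            compute_exg(np.zeros((4, 4)))


class TestBinarize:
    def test_threshold_is_strict(self):
        exg = np.array([[0.05, 0.1, 0.15, 0.5]])
        np.testing.assert_array_equal(binarize(exg, 0.1),
                                      [[False, False, True, True]])

    def test_all_zero(self):
        assert not binarize(np.zeros((5, 5))).any()


class TestExtractObjects:
    def test_solid_square(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        objs = extract_objects(mask)
        assert len(objs) == 1
        o = objs[0]
        assert o.area == 9
        assert o.perimeter == 8      # all but the centre pixel touch background
        assert o.centroid_px == (3.0, 3.0)

    def test_connectivity_modes(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:3, 1:3] = True
        mask[3:5, 3:5] = True        # touches the first square only diagonally
        assert len(extract_objects(mask, connectivity=8)) == 1
        assert len(extract_objects(mask, connectivity=4)) == 2

    def test_empty_mask(self):
        assert extract_objects(np.zeros((4, 4), dtype=bool)) == []


def obj(label, area, perimeter):
    return PlantObject(label=label, coords=np.empty((0, 2), dtype=int),
                       area=area, perimeter=perimeter, centroid_px=(0.0, 0.0))


class TestFilterObjects:
    def test_small_area_removed_relative_to_mean(self):
        objs = [obj(1, 200, 60), obj(2, 200, 60), obj(3, 20, 6)]
        # equal P/A = 0.3 so the shape criterion removes nothing
        kept = filter_objects(objs)
        assert [o.label for o in kept] == [1, 2]  # threshold = 0.3 * 140 = 42

    def test_all_at_mean_survive(self):
        objs = [obj(i, 100, 30) for i in range(3)]
        assert len(filter_objects(objs)) == 3

    def test_single_object_never_removed(self):
        assert len(filter_objects([obj(1, 5, 4)])) == 1

    def test_literal_shape_mode_removes_compact_objects(self):
        # same area; one object far more compact (low P/A) than the others
        objs = [obj(1, 100, 40), obj(2, 100, 40), obj(3, 100, 4)]
        kept = filter_objects(objs, shape_filter_mode="literal_less_than")
        assert [o.label for o in kept] == [1, 2]

    def test_thin_object_mode_removes_high_ratio_objects(self):
        objs = [obj(1, 100, 30), obj(2, 100, 30), obj(3, 100, 30),
                obj(4, 100, 500)]  # P/A = 5 vs 0.3: past mean/0.3 = 4.92
        kept = filter_objects(objs, shape_filter_mode="thin_object")
        assert [o.label for o in kept] == [1, 2, 3]

    def test_largest_object_always_kept(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            objs = [obj(i, int(a), int(a) // 3 + 1)
                    for i, a in enumerate(rng.integers(5, 500, size=8))]
            kept = filter_objects(objs)
            assert max(o.area for o in objs) in {o.area for o in kept}
            assert len(kept) <= len(objs)

    def test_empty_passes_through(self):
        assert filter_objects([]) == []


class TestMergeFragments:
    def test_nearby_squares_merge(self):
        mask = np.zeros((20, 30), dtype=bool)
        mask[5:10, 5:10] = True
        mask[5:10, 14:19] = True     # 4-px gap
        objs = merge_fragments(mask, dilation_size=10)
        assert len(objs) == 1
        assert objs[0].area == 50    # union of the original pixels only

    def test_distant_squares_stay_separate(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[5:10, 5:10] = True
        mask[5:10, 40:45] = True     # 30-px gap, beyond the dilation reach
        assert len(merge_fragments(mask, dilation_size=10)) == 2

    def test_isolated_object_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:9, 4:9] = True
        before = extract_objects(mask)[0]
        after = merge_fragments(mask, dilation_size=10)
        assert len(after) == 1
        assert after[0].area == before.area
        assert after[0].perimeter == before.perimeter
        assert after[0].centroid_px == before.centroid_px

    def test_merge_never_increases_count_and_conserves_pixels(self):
        rng = np.random.default_rng(3)
        mask = rng.random((60, 60)) > 0.85
        before = extract_objects(mask)
        after = merge_fragments(mask, dilation_size=5)
        assert len(after) <= len(before)
        assert sum(o.area for o in after) == int(mask.sum())


class TestDetectPlants:
    def test_all_soil_image_yields_nothing(self, cam_small):
        soil = np.full((100, 100, 3), (128, 100, 82), dtype=np.uint8)
        assert detect_plants(soil, cam_small) == []

    def test_fragmented_plant_detected_as_one(self, cam_small):
        # three green fragments within the dilation reach of one another
        img = np.full((60, 60, 3), (128, 100, 82), dtype=np.uint8)
        for r0, c0 in [(20, 18), (26, 30), (34, 22)]:
            img[r0:r0 + 5, c0:c0 + 5] = (72, 158, 62)
        objs = detect_plants(img, cam_small, dilation_size=10)
        assert len(objs) == 1

    def test_count_matches_truth_on_clean_scene(self, clean_scene, cam_small):
        _, img, truth = clean_scene
        objs = detect_plants(img, cam_small)
        assert len(objs) == truth.n_plants

    def test_detector_is_sklearn_compatible(self, cam_small):
        det = PlantDetector(cam_small, exg_threshold=0.2)
        assert det.get_params()["exg_threshold"] == 0.2
        det.set_params(exg_threshold=0.1).fit()
        assert det.is_fitted_
        clone_params = PlantDetector(cam_small).get_params()
        assert "dilation_size" in clone_params

    def test_ground_centroids_populated_and_corrected(self, clean_scene, cam_small):
        _, img, truth = clean_scene
        objs = detect_plants(img, cam_small)
        o = max(objs, key=lambda o: abs(o.centroid_ground_apparent[1]))
        # correction pulls the far object toward nadir
        assert abs(o.centroid_ground[1]) < abs(o.centroid_ground_apparent[1])
        f = cam_small.parallax_factor
        assert o.centroid_ground[1] == pytest.approx(
            o.centroid_ground_apparent[1] * f)
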