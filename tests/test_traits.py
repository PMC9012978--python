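"""Trait extraction against analytic shapes and exact invariances."""

import numpy as np
import pytest

from rootclass.synthetic_roots import BinaryRootImage
from rootclass.traits import (ExtractionSettings, ScaleMarker, TRAIT_NAMES,
                              batch_extract, binarize, extract_traits,
                              px_per_mm_from_marker, skeletonize_and_prune)
from tests.conftest import bar_image


@pytest.mark.parametrize("px,mm,expected", [(100, 10, 10.0), (57, 10, 5.7)])
def test_scale_marker_ratio(px, mm, expected):
    assert px_per_mm_from_marker(ScaleMarker(px, mm)) == pytest.approx(expected)


def test_scale_marker_rejects_nonpositive():
    with pytest.raises(ValueError):
        px_per_mm_from_marker(ScaleMarker(0, 10))


class TestBinarize:
    def test_white_root_on_black_is_unchanged(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 9:11] = 255
        out = binarize(mask, 200)
        assert np.array_equal(out, mask == 255)

    def test_black_root_on_white_polarity_autodetected(self):
        raster = np.full((20, 20), 255, dtype=np.uint8)
        raster[5:15, 9:11] = 0
        out = binarize(raster, 200)
        assert np.array_equal(out, raster == 0)

    def test_uniform_raster_has_no_foreground(self):
        with pytest.raises(ValueError, match="200"):
            binarize(np.full((10, 10), 255, dtype=np.uint8), 200)

    def test_gradient_strip_foreground_is_above_threshold(self):
        strip = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        out = binarize(strip, 200)
        assert np.array_equal(out, strip > 200)


class TestSkeleton:
    def test_bar_skeleton_is_single_path_with_half_width_radius(self):
        im = bar_image(length_px=100, width_px=5)
        skel, radius = skeletonize_and_prune(im, 2)
        n = skel.sum()
        assert 90 <= n <= 105  # a single ~100 px path
        interior = radius[skel][5:-5]
        assert np.allclose(interior, 2.5, atol=0.6)

    def test_plus_sign_has_four_tips_and_one_branch_cluster(self):
        arr = np.zeros((21, 21), dtype=bool)
        arr[10, 3:18] = True
        arr[3:18, 10] = True
        im = BinaryRootImage(arr, 10.0, "plus")
        tv = extract_traits(im, ExtractionSettings(pruning_threshold_px=0))
        assert tv["tip_count"] == 4
        assert tv["branch_point_count"] == 1

    def test_short_spur_removed_by_pruning(self):
        arr = np.zeros((30, 30), dtype=bool)
        arr[5:25, 15] = True  # main bar
        arr[14, 16:18] = True  # 2-px spur
        im = BinaryRootImage(arr, 10.0, "spur")
        skel, _ = skeletonize_and_prune(im, 2)
        from rootclass.traits import _neighbor_count
        nc = _neighbor_count(skel) * skel
        assert np.sum(nc == 1) == 2  # spur gone, two bar endpoints remain
        skel0, _ = skeletonize_and_prune(im, 0)
        nc0 = _neighbor_count(skel0) * skel0
        assert np.sum(nc0 == 1) == 3  # unpruned skeleton keeps the spur tip


class TestExtractTraits:
    def test_bar_geometry(self):
        tv = extract_traits(bar_image(length_px=100, width_px=5, px_per_mm=10))
        assert tv["depth_mm"] == pytest.approx(10.0)
        assert tv["max_width_mm"] == pytest.approx(0.5)
        assert tv["tip_count"] == 2
        assert tv["branch_point_count"] == 0
        assert tv["hole_count"] == 0
        assert tv["median_root_count"] == 1
        assert tv["steep_angle_freq"] > 0.9  # vertical bar
        assert tv["network_area_mm2"] == pytest.approx(5.0)

    def test_annulus_has_one_hole_with_inner_area(self):
        arr = np.zeros((40, 40), dtype=bool)
        arr[10:30, 10:30] = True
        arr[15:25, 15:25] = False  # 10x10 void
        im = BinaryRootImage(arr, 10.0, "annulus")
        tv = extract_traits(im)
        assert tv["hole_count"] == 1
        assert tv["total_hole_area_mm2"] == pytest.approx(1.0)  # 100 px / 100
        assert tv["avg_hole_size_mm2"] == pytest.approx(1.0)

    def test_solidity_in_unit_interval_and_consistent(self):
        tv = extract_traits(bar_image())
        assert 0 < tv["solidity"] <= 1
        assert tv["solidity"] == pytest.approx(
            tv["network_area_mm2"] / tv["convex_hull_area_mm2"])

    def test_rotating_90_degrees_swaps_depth_and_width(self):
        from rootclass.synthetic_roots import DEFAULT_SPECS, generate_root_image
        im, _ = generate_root_image(DEFAULT_SPECS["B"], px_per_mm=4.0, seed=2)
        rot = BinaryRootImage(im.pixels.T.copy(), im.px_per_mm, "rot")
        a, b = extract_traits(im), extract_traits(rot)
        assert b["depth_mm"] == pytest.approx(a["max_width_mm"])
        assert b["max_width_mm"] == pytest.approx(a["depth_mm"])
        assert b["total_length_mm"] == pytest.approx(a["total_length_mm"],
                                                     rel=0.01)

    def test_traits_invariant_under_180_degree_rotation(self):
        from rootclass.synthetic_roots import DEFAULT_SPECS, generate_root_image
        im, _ = generate_root_image(DEFAULT_SPECS["TB"], px_per_mm=4.0, seed=4)
        rot = BinaryRootImage(im.pixels[::-1, ::-1].copy(), im.px_per_mm, "r180")
        a, b = extract_traits(im), extract_traits(rot)
        # mask-level traits are exactly invariant; skeleton-level traits
        # only to thinning asymmetry (~1%)
        for name in ("depth_mm", "max_width_mm", "network_area_mm2",
                     "hole_count", "convex_hull_area_mm2", "solidity"):
            assert b[name] == pytest.approx(a[name], rel=1e-9), name
        assert b["total_length_mm"] == pytest.approx(a["total_length_mm"],
                                                     rel=0.01)
        assert b["steep_angle_freq"] == pytest.approx(a["steep_angle_freq"],
                                                      abs=0.03)
        assert b["shallow_angle_freq"] == pytest.approx(
            a["shallow_angle_freq"], abs=0.03)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_diameter_range_additivity(self, seed):
        from rootclass.synthetic_roots import DEFAULT_SPECS, generate_root_image
        im, _ = generate_root_image(DEFAULT_SPECS["B"], px_per_mm=4.0,
                                    seed=seed)
        tv = extract_traits(im)
        for total, parts in [
                ("total_length_mm", ["length_1_mm", "length_2_mm", "length_3_mm"]),
                ("surface_area_mm2", ["surface_area_1_mm2", "surface_area_2_mm2",
                                      "surface_area_3_mm2"]),
                ("volume_mm3", ["volume_1_mm3", "volume_2_mm3", "volume_3_mm3"])]:
            assert sum(tv[p] for p in parts) == pytest.approx(
                tv[total], rel=1e-6), total

    def test_scale_covariance_of_units(self):
        """Doubling px_per_mm on the same raster halves lengths, quarters
        areas, and eighths volumes exactly."""
        im5 = bar_image(px_per_mm=5.0)
        im10 = bar_image(px_per_mm=10.0)
        a, b = extract_traits(im5), extract_traits(im10)
        assert b["total_length_mm"] == pytest.approx(a["total_length_mm"] / 2)
        assert b["network_area_mm2"] == pytest.approx(a["network_area_mm2"] / 4)
        assert b["volume_mm3"] == pytest.approx(a["volume_mm3"] / 8)
        assert b["tip_count"] == a["tip_count"]

    def test_angle_frequencies_sum_to_one(self):
        from rootclass.synthetic_roots import DEFAULT_SPECS, generate_root_image
        im, _ = generate_root_image(DEFAULT_SPECS["B"], px_per_mm=4.0, seed=9)
        tv = extract_traits(im)
        total = (tv["shallow_angle_freq"] + tv["medium_angle_freq"]
                 + tv["steep_angle_freq"])
        assert total == pytest.approx(1.0)

    def test_single_pixel_image_is_flagged_degenerate(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[2, 2] = True
        with pytest.warns(UserWarning, match="degenerate"):
            tv = extract_traits(BinaryRootImage(arr, 10.0, "dot"))
        assert tv.degenerate
        assert tv["total_length_mm"] == 0.0
        assert tv["steep_angle_freq"] == 0.0

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            extract_traits(BinaryRootImage(np.zeros((5, 5), bool), 10.0, "e"))


class TestBatchExtract:
    def test_row_order_and_full_header(self):
        imgs = [bar_image(), bar_image(length_px=50)]
        imgs[1].image_id = "bar2"
        table, failures = batch_extract(imgs)
        assert not failures
        assert list(table["image_id"]) == ["bar", "bar2"]
        assert list(table.columns) == ["image_id", *TRAIT_NAMES]

    def test_empty_input_gives_empty_table_with_header(self):
        table, failures = batch_extract([])
        assert len(table) == 0 and not failures
        assert list(table.columns) == ["image_id", *TRAIT_NAMES]

    def test_corrupt_image_reported_not_dropped_silently(self):
        good = bar_image()
        bad = BinaryRootImage(np.ones((5, 5), bool), 10.0, "ok_shape")
        bad.pixels = np.zeros((5, 5), bool)  # empty foreground
        bad.image_id = "corrupt"
        table, failures = batch_extract([good, bad, bar_image()])
        assert len(table) == 2
        assert len(failures) == 1 and failures[0][0] == "corrupt"
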