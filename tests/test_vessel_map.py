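"""Binarization, cleaning, skeleton, caliber and micro/macro decomposition."""

import numpy as np
import pytest

from octaquant import (
    EnFaceImage,
    SyntheticSpec,
    binarize,
    build_vessel_maps,
    classify_vessels,
    estimate_caliber,
    generate_tree,
    min_component_px_for_caliber,
    preprocess,
    remove_nonvascular,
    skeletonize,
)
from octaquant.vessel_map import DEFAULT_PITCH_MM


def as_image(pixels, **kw):
    return EnFaceImage(np.asarray(pixels, dtype=float), **kw)


class TestPreprocess:
    def test_output_in_unit_range_and_shape_preserved(self):
        rng = np.random.default_rng(0)
        img = as_image(rng.random((128, 128)))
        out = preprocess(img)
        assert out.pixels.shape == (128, 128)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_idempotent_on_normalized_input(self, clean_tree):
        img, _ = clean_tree
        once = preprocess(img)
        twice = preprocess(once)
        assert np.abs(twice.pixels - once.pixels).max() <= 1e-6

    def test_invert_puts_vessels_bright(self, clean_tree):
        img, gt = clean_tree
        dark_vessels = as_image(1.0 - img.pixels)  # inverted-polarity device output
        out = preprocess(dark_vessels, invert=True)
        assert out.pixels[gt.vessel_mask].mean() > out.pixels[~gt.vessel_mask].mean()

    def test_constant_image_warns_and_passes_through(self):
        img = as_image(np.full((64, 64), 0.5))
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess(img)
        assert np.array_equal(out.pixels, img.pixels)


class TestBinarize:
    def test_bimodal_recovers_ground_truth_exactly(self, clean_tree):
        img, gt = clean_tree  # vessels 0.9, background 0.1, no noise
        assert np.array_equal(binarize(img), gt.vessel_mask)

    def test_all_zero_image_gives_empty_mask(self):
        assert not binarize(as_image(np.zeros((64, 64)))).any()

    def test_noisy_mask_fraction_within_tolerance(self, noisy_tree):
        img, _ = noisy_tree
        assert binarize(img).mean() == pytest.approx(0.3, abs=0.05)

    def test_fixed_method_requires_threshold(self):
        img = as_image(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="fixed_threshold"):
            binarize(img, method="fixed")

    def test_fixed_threshold_is_strict_inequality(self):
        img = as_image([[0.2, 0.5], [0.5, 0.8]])
        mask = binarize(img, method="fixed", fixed_threshold=0.5)
        assert mask.tolist() == [[False, False], [False, True]]


class TestRemoveNonvascular:
    def test_speckle_removed_vessel_kept(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:8, 5] = True  # 3-px speckle
        mask[20:25, 0:50] = True  # 250-px vessel
        out = remove_nonvascular(mask, min_component_px=20)
        assert not out[5:8, 5].any()
        assert out[20:25, 0:50].all()

    def test_min_zero_is_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random((64, 64)) > 0.7
        assert np.array_equal(remove_nonvascular(mask, min_component_px=0), mask)

    def test_default_min_size_matches_25um_disk(self, pitch):
        # area of a 25 μm disk at 3/512 mm pitch: pi * (12.5/5.859)^2 ~ 14.3 px
        assert min_component_px_for_caliber(pitch) == 15

    def test_cleaning_salt_noise_raises_jaccard(self, clean_tree):
        _, gt = clean_tree
        truth = gt.vessel_mask
        rng = np.random.default_rng(5)
        corrupted = truth | (rng.random(truth.shape) < 0.002)

        def jaccard(a, b):
            return (a & b).sum() / (a | b).sum()

        cleaned = remove_nonvascular(corrupted, pixel_pitch_mm=DEFAULT_PITCH_MM)
        assert jaccard(cleaned, truth) > jaccard(corrupted, truth)


class TestSkeletonize:
    def test_thick_bar_thins_to_single_line(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[10:15, 5:105] = True  # 5 px thick, 100 px long
        skel = skeletonize(mask)
        assert skel.sum() == pytest.approx(100, abs=8)
        assert (skel.sum(axis=0) <= 1).all()  # 1-px wide everywhere

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((32, 32), dtype=bool)).any()

    def test_idempotent(self, clean_tree):
        img, gt = clean_tree
        skel = skeletonize(gt.vessel_mask)
        assert np.array_equal(skeletonize(skel), skel)

    def test_subset_of_mask(self, clean_tree):
        _, gt = clean_tree
        skel = skeletonize(gt.vessel_mask)
        assert not (skel & ~gt.vessel_mask).any()


class TestEstimateCaliber:
    def test_bar_of_known_thickness(self, pitch):
        mask = np.zeros((40, 120), dtype=bool)
        mask[10:17, 5:105] = True  # 7 px thick
        skel = np.zeros_like(mask)
        skel[13, 20:90] = True  # interior centerline
        cal = estimate_caliber(mask, skel, pitch)
        interior = cal[13, 30:80]
        assert np.all(interior >= 7 * pitch * 1000 - 1e-9)
        assert np.all(interior <= 8 * pitch * 1000 + 1e-9)

    def test_one_px_line_reads_twice_pitch(self, pitch):
        mask = np.zeros((20, 60), dtype=bool)
        mask[10, 5:55] = True
        skel = mask.copy()
        cal = estimate_caliber(mask, skel, pitch)
        assert cal[10, 30] == pytest.approx(2 * pitch * 1000)  # ~11.7 μm

    def test_disk_center_reads_its_diameter(self, pitch):
        g = 64
        rr, cc = np.mgrid[0:g, 0:g]
        radius = 10
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= radius**2
        skel = np.zeros_like(mask)
        skel[32, 32] = True
        cal = estimate_caliber(mask, skel, pitch)
        d_px = cal[32, 32] / (pitch * 1000)
        assert d_px == pytest.approx(2 * radius + 1, abs=2)

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((8, 8), dtype=bool)
        skel = np.zeros((8, 8), dtype=bool)
        skel[1, 1] = True
        with pytest.raises(ValueError, match="subset"):
            estimate_caliber(mask, skel, DEFAULT_PITCH_MM)


class TestClassifyVessels:
    @staticmethod
    def trunk_and_mesh(pitch):
        """One wide trunk (10 px ~ 59 μm) and thin 2-px capillaries."""
        mask = np.zeros((128, 128), dtype=bool)
        mask[20:30, :] = True  # trunk
        for col in range(10, 120, 16):
            mask[60:120, col : col + 2] = True  # mesh
        skel = skeletonize(mask)
        cal = estimate_caliber(mask, skel, pitch)
        return mask, skel, cal

    def test_trunk_macro_mesh_micro_union_total(self, pitch):
        mask, skel, cal = self.trunk_and_mesh(pitch)
        micro, macro = classify_vessels(mask, skel, cal, threshold_um=25.0)
        assert macro[25, 40:90].all()  # trunk interior
        assert micro[90, 10:12].all()  # mesh
        assert np.array_equal(micro | macro, mask)
        assert not (micro & macro).any()

    def test_all_below_threshold_means_no_macro(self, pitch):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 5:60] = True  # ~6 μm, far below 25 μm
        skel = mask.copy()
        cal = estimate_caliber(mask, skel, pitch)
        micro, macro = classify_vessels(mask, skel, cal)
        assert not macro.any() and np.array_equal(micro, mask)

    def test_infinite_threshold_empties_macro(self, pitch):
        mask, skel, cal = self.trunk_and_mesh(pitch)
        micro, macro = classify_vessels(mask, skel, cal, threshold_um=np.inf)
        assert not macro.any() and np.array_equal(micro, mask)

    def test_empty_skeleton_warns_all_micro(self):
        mask = np.ones((16, 16), dtype=bool)
        skel = np.zeros_like(mask)
        with pytest.warns(UserWarning, match="micro"):
            micro, macro = classify_vessels(mask, skel, np.full(mask.shape, np.nan))
        assert np.array_equal(micro, mask) and not macro.any()


class TestFullChain:
    def test_decomposition_invariant_on_synthetic(self, noisy_tree):
        img, _ = noisy_tree
        maps = build_vessel_maps(img)
        assert maps.micro.sum() + maps.macro.sum() == maps.total.sum()
        assert not (maps.skeleton & ~maps.total).any()

    def test_noise_free_recovery_within_tolerance(self, clean_tree):
        img, gt = clean_tree
        maps = build_vessel_maps(img)
        assert abs(maps.total.mean() - gt.vessel_mask.mean()) <= 0.02

    def test_rotation_robustness_exact(self):
        spec = SyntheticSpec(target_perfusion=0.25, noise=0.1, seed=13, grid_px=128)
        img, _ = generate_tree(spec)
        rot = EnFaceImage(np.rot90(img.pixels).copy(), pixel_pitch_mm=img.pixel_pitch_mm)
        assert build_vessel_maps(rot).total.mean() == build_vessel_maps(img).total.mean()
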