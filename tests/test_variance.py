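"""Unit and property tests for the segmentation pipeline stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vmseg import (
    EliminationMask,
    RetinalImage,
    SegmentationMask,
    VarianceMap,
    VMsegParams,
    binarize,
    bilateral_smooth,
    combine_variance_maps,
    fill_and_filter,
    local_variance_map,
    modify_variance_map,
    morphology_clean,
    normalize_image,
    segment,
)
from vmseg.variance import CROSS_KERNEL_5


def brute_force_variance(px: np.ndarray, window: int) -> np.ndarray:
    """Independent oracle: double-loop population variance with reflect pad."""
    r = window // 2
    padded = np.pad(px, r, mode="reflect")
    out = np.empty_like(px, dtype=float)
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            patch = padded[i:i + window, j:j + window]
            out[i, j] = patch.var()
    return out


class TestNormalize:
    def test_linear_map_value(self):
        px = np.full((64, 64), 60.0)
        px[0, 0], px[0, 1] = 10.0, 110.0
        out = normalize_image(RetinalImage(px))
        assert out.pixels[1, 1] == pytest.approx((60 - 10) * 255 / 100)

    def test_constant_maps_to_zero(self):
        out = normalize_image(RetinalImage(np.full((64, 64), 42.0)))
        assert np.all(out.pixels == 0)

    def test_matches_direct_formula(self, rng):
        px = rng.uniform(0, 255, (64, 64))
        out = normalize_image(RetinalImage(px))
        expected = (px - px.min()) * 255.0 / (px.max() - px.min())
        assert np.allclose(out.pixels, expected)


class TestBilateral:
    def test_constant_is_fixed_point(self):
        out = bilateral_smooth(RetinalImage(np.full((64, 64), 99.0)))
        assert np.allclose(out.pixels, 99.0, atol=1e-6)

    def test_step_edge_location_preserved(self):
        px = np.zeros((64, 64))
        px[:, 32:] = 200.0
        out = bilateral_smooth(RetinalImage(px))
        grad_in = np.abs(np.diff(px[32])).argmax()
        grad_out = np.abs(np.diff(out.pixels[32])).argmax()
        assert grad_out == grad_in

    def test_salt_noise_variance_reduced(self, rng):
        px = np.full((64, 64), 100.0)
        idx = rng.integers(0, 64, (60, 2))
        px[idx[:, 0], idx[:, 1]] = 130.0
        out = bilateral_smooth(RetinalImage(px))
        assert out.pixels.var() < px.var()

    def test_output_within_input_range(self, rng):
        px = rng.uniform(40, 210, (64, 64))
        out = bilateral_smooth(RetinalImage(px))
        assert out.pixels.min() >= px.min() - 1e-9
        assert out.pixels.max() <= px.max() + 1e-9

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            bilateral_smooth(RetinalImage(np.zeros((64, 64))), diameter=8)


class TestLocalVarianceMap:
    def test_constant_image_zero_map(self):
        vm = local_variance_map(RetinalImage(np.full((64, 64), 77.0)), 3)
        assert np.all(vm.values == 0)

    def test_checkerboard_closed_form(self):
        """3x3 window on a 0/255 checkerboard: var = 255^2*k*(9-k)/81 with
        k in {4,5} the number of 255s in the window."""
        px = 255.0 * (np.indices((64, 64)).sum(axis=0) % 2)
        vm = local_variance_map(RetinalImage(px), 3)
        interior = vm.values[1:-1, 1:-1]
        expected = {255.0**2 * k * (9 - k) / 81 for k in (4, 5)}
        got = set(np.round(interior, 6).ravel())
        assert got == {round(e, 6) for e in expected}

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_brute_force_oracle(self, rng, window):
        px = rng.uniform(0, 255, (32, 32))
        vm = local_variance_map(RetinalImage(px), window)
        oracle = brute_force_variance(px, window)
        r = window // 2
        assert np.allclose(vm.values[r:-r, r:-r], oracle[r:-r, r:-r], atol=1e-6)

    def test_invalid_window_rejected(self):
        img = RetinalImage(np.zeros((64, 64)))
        for w in (2, 4, 9):
            with pytest.raises(ValueError):
                local_variance_map(img, w)


class TestCombine:
    def test_singleton_unchanged(self, rng):
        vm = VarianceMap(rng.uniform(0, 50, (32, 32)))
        out = combine_variance_maps([vm])
        assert np.allclose(out.values, vm.values)

    def test_elementwise_mean(self, rng):
        a, b, c = (rng.uniform(0, 50, (32, 32)) for _ in range(3))
        out = combine_variance_maps([VarianceMap(a), VarianceMap(b), VarianceMap(c)])
        assert np.allclose(out.values, (a + b + c) / 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_variance_maps(
                [VarianceMap(np.zeros((32, 32))), VarianceMap(np.zeros((16, 16)))])


class TestModifyVarianceMap:
    def test_constant_dark_image_all_zero(self):
        img = RetinalImage(np.full((64, 64), 10.0))
        vm = local_variance_map(img, 3)
        out = modify_variance_map(vm, img, intensity_threshold=75)
        assert out.stage == "modified"
        assert np.all(out.values == 0)

    def test_bright_pixel_overridden_to_255(self, rng):
        px = rng.uniform(0, 50, (64, 64))
        px[10, 10] = 255.0
        img = RetinalImage(px)
        out = modify_variance_map(local_variance_map(img, 3), img, 75)
        assert out.values[10, 10] == 255.0

    def test_noisy_patch_above_flat_patch(self, rng):
        """Textured areas must carry higher modified values than flat ones."""
        px = np.full((64, 64), 30.0)
        px[:, 32:] = np.clip(30.0 + rng.normal(0, 15, (64, 32)), 0, 70)
        img = RetinalImage(px)
        out = modify_variance_map(local_variance_map(img, 3), img, 200)
        assert out.values[:, 34:].mean() > out.values[:, :30].mean()


class TestMorphology:
    @staticmethod
    def direct_morph(values, footprint, op):
        """Independent oracle: explicit min/max filter with reflect pad."""
        n = footprint.shape[0] // 2
        padded = np.pad(values, n, mode="reflect")
        out = np.empty_like(values)
        fn = np.max if op == "dilate" else np.min
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                patch = padded[i:i + 2 * n + 1, j:j + 2 * n + 1]
                out[i, j] = fn(patch[footprint])
        return out

    def test_zero_iterations_identity(self, rng):
        vm = VarianceMap(rng.uniform(0, 255, (32, 32)), stage="modified")
        out = morphology_clean(vm, iterations=0)
        assert np.array_equal(out.values, vm.values)

    def test_isolated_bright_speck_removed(self):
        values = np.zeros((15, 15))
        values[7, 7] = 200.0
        vm = VarianceMap(values, stage="modified")
        out = morphology_clean(vm, iterations=1)
        d = self.direct_morph(values, CROSS_KERNEL_5, "dilate")
        e = self.direct_morph(d, CROSS_KERNEL_5, "erode")
        e2 = self.direct_morph(e, CROSS_KERNEL_5, "erode")
        expected = self.direct_morph(e2, CROSS_KERNEL_5, "dilate")
        assert np.array_equal(out.values, expected)
        assert np.all(out.values == 0)  # the speck is gone

    def test_single_dark_hole_filled(self):
        values = np.full((15, 15), 200.0)
        values[7, 7] = 0.0
        out = morphology_clean(VarianceMap(values, stage="modified"), iterations=1)
        assert np.all(out.values == 200.0)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            morphology_clean(
                VarianceMap(np.zeros((15, 15)), stage="modified"), iterations=-1)


class TestBinarizeAndFilter:
    def test_strict_inequality_at_threshold(self):
        values = np.zeros((64, 64))
        values[0, :] = 10.0
        values[1, :] = 17.0
        values[2, :] = 20.0
        mask = binarize(VarianceMap(values, stage="modified"), 17.0)
        assert mask.nonperfusion[0].all()
        assert not mask.nonperfusion[1].any()
        assert not mask.nonperfusion[2].any()

    def test_all_zero_map_all_true(self):
        mask = binarize(VarianceMap(np.zeros((64, 64)), stage="modified"), 17.0)
        assert mask.nonperfusion.all()

    def test_all_255_map_all_false(self):
        mask = binarize(VarianceMap(np.full((64, 64), 255.0), stage="modified"), 17.0)
        assert not mask.nonperfusion.any()

    def test_blob_with_hole_filled_and_kept(self):
        m = np.zeros((64, 64), dtype=bool)
        m[10:30, 10:27] = True          # 340 px
        m[15:20, 15:19] = False         # 20-px hole -> 320 px solid after fill
        out = fill_and_filter(SegmentationMask(m), 250)
        assert out.nonperfusion[15:20, 15:19].all()
        assert out.area == 20 * 17

    @pytest.mark.parametrize("area,kept", [(249, False), (250, True)])
    def test_size_threshold_boundary(self, area, kept):
        m = np.zeros((64, 64), dtype=bool)
        # solid rectangle of exactly `area` pixels
        m[5:5 + (area // 10), 5:15] = True
        m[5 + area // 10, 5:5 + area % 10] = True
        assert m.sum() == area
        out = fill_and_filter(SegmentationMask(m), 250)
        assert out.nonperfusion.any() == kept

    def test_idempotent(self, rng):
        m = rng.random((128, 128)) > 0.45
        once = fill_and_filter(SegmentationMask(m), 250)
        twice = fill_and_filter(once, 250)
        assert np.array_equal(once.nonperfusion, twice.nonperfusion)


class TestSegmentPipeline:
    def test_uniform_dark_image_whole_frame(self):
        mask = segment(RetinalImage(np.full((64, 64), 15.0)))
        assert mask.nonperfusion.all()

    def test_dense_bright_noise_empty_mask(self, rng):
        px = rng.integers(0, 256, (128, 128)).astype(float)
        assert segment(RetinalImage(px)).area == 0

    def test_deterministic_bitwise(self, small_phantom):
        m1 = segment(small_phantom.image, small_phantom.elim)
        m2 = segment(small_phantom.image, small_phantom.elim)
        assert np.array_equal(m1.nonperfusion, m2.nonperfusion)

    def test_mask_disjoint_from_elimination(self, small_phantom):
        mask = segment(small_phantom.image, small_phantom.elim)
        assert not np.any(mask.nonperfusion & small_phantom.elim.excluded)

    def test_phantom_patch_recovered(self, small_phantom):
        from vmseg import confusion, dice
        mask = segment(small_phantom.image, small_phantom.elim)
        d = dice(confusion(mask, small_phantom.truth, small_phantom.elim))
        assert d >= 0.8

    def test_variance_threshold_monotone_on_binarized_foreground(self, small_phantom):
        """Raising the variance threshold can only grow the pre-filter
        binarized candidate set (set inclusion)."""
        from vmseg.variance import (
            _bilateral, normalize_image as norm_fn)
        from vmseg import (combine_variance_maps, local_variance_map,
                           modify_variance_map, morphology_clean)
        p = VMsegParams()
        norm = norm_fn(small_phantom.image)
        sm = bilateral_smooth(norm)
        combined = combine_variance_maps(
            [local_variance_map(sm, k) for k in p.kernel_sizes])
        modified = modify_variance_map(combined, norm, p.intensity_threshold)
        smoothed = VarianceMap(_bilateral(modified.values, 9, 40.0),
                               stage="modified")
        cleaned = morphology_clean(smoothed, iterations=1)
        prev = binarize(cleaned, 10.0).nonperfusion
        for t in (14.0, 17.0, 22.0, 30.0):
            cur = binarize(cleaned, t).nonperfusion
            assert np.all(cur[prev])  # set inclusion
            prev = cur

    def test_shape_mismatch_rejected(self, small_phantom):
        bad = EliminationMask(np.zeros((32, 32), dtype=bool))
        with pytest.raises(ValueError):
            segment(small_phantom.image, bad)


class TestParams:
    def test_defaults_are_published_optimum(self):
        p = VMsegParams()
        assert p.kernel_sizes == (3, 5)
        assert p.variance_threshold == 17.0
        assert p.intensity_threshold == 75.0
        assert p.morph_iterations == 1
        assert p.size_threshold_px == 250

    @pytest.mark.parametrize("kwargs", [
        {"kernel_sizes": ()},
        {"kernel_sizes": (4,)},
        {"variance_threshold": 0.0},
        {"intensity_threshold": 300.0},
        {"morph_iterations": -1},
        {"size_threshold_px": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VMsegParams(**kwargs)

    def test_roundtrip_dict(self):
        p = VMsegParams(kernel_sizes=(3, 7), variance_threshold=12.5)
        assert VMsegParams.from_dict(p.to_dict()) == p


@settings(deadline=None, max_examples=25)
@given(hnp.arrays(np.float64, (32, 32), elements=st.floats(0, 255)),
       st.sampled_from([3, 5, 7]))
def test_variance_map_property_matches_oracle(px, window):
    """Convolution-based variance equals the double-loop oracle on the
    interior for arbitrary images (property-based)."""
    vm = local_variance_map(RetinalImage(np.asarray(px)), window)
    oracle = brute_force_variance(np.asarray(px), window)
    r = window // 2
    assert np.allclose(vm.values[r:-r, r:-r], oracle[r:-r, r:-r], atol=1e-6)
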