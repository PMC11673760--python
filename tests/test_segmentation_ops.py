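"""Unit tests for the individual segmentation-chain operations."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import morphology as skmorph
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from bubblekit import (
    FilterCriteria,
    ImageFrame,
    SegmentationParams,
    binarize,
    convert_to_8bit,
    filter_particles,
    gaussian_blur,
    measure_particles,
    remove_outliers,
    segment_image,
    subtract_background,
    watershed_split,
)
from bubblekit.segmentation import SegmentationError

from conftest import disk_mask


# ---------------------------------------------------------------------------
# convert_to_8bit
# ---------------------------------------------------------------------------

class TestConvertTo8Bit:
    def test_8bit_input_is_identity(self):
        arr = np.arange(256, dtype=np.uint8).reshape(16, 16)
        f = ImageFrame(arr, bit_depth=8, pixel_size_um=0.2)
        out = convert_to_8bit(f)
        assert np.array_equal(out.pixels, arr)
        assert out.pixel_size_um == 0.2

    def test_endpoints_map_to_full_range(self):
        arr = np.array([[0, 65535], [65535, 0]], dtype=np.uint16)
        out = convert_to_8bit(ImageFrame(arr))
        assert np.array_equal(out.pixels, np.array([[0, 255], [255, 0]], dtype=np.uint8))

    def test_half_value_rounds_away_from_zero(self):
        # min 0, max 1000: pixel 500 -> 500/1000*255 = 127.5 -> 128
        arr = np.array([[0, 500, 1000]], dtype=np.uint16)
        out = convert_to_8bit(ImageFrame(arr))
        assert out.pixels[0, 1] == 128

    def test_constant_frame_warns_and_zeros(self):
        arr = np.full((4, 4), 300, dtype=np.uint16)
        with pytest.warns(UserWarning):
            out = convert_to_8bit(ImageFrame(arr))
        assert not out.pixels.any()

    def test_fixed_display_range_preserves_ratios(self):
        a = ImageFrame(np.full((4, 4), 2570, dtype=np.uint16))
        b = ImageFrame(np.full((4, 4), 5140, dtype=np.uint16))
        ca = convert_to_8bit(a, display_range=(0, 65535))
        cb = convert_to_8bit(b, display_range=(0, 65535))
        assert cb.pixels[0, 0] == 2 * ca.pixels[0, 0]


# ---------------------------------------------------------------------------
# gaussian_blur / subtract_background
# ---------------------------------------------------------------------------

class TestBlur:
    def test_constant_frame_unchanged(self):
        f = ImageFrame(np.full((32, 32), 7000, dtype=np.uint16))
        assert np.array_equal(gaussian_blur(f, 3.0).pixels, f.pixels)

    def test_sigma_zero_is_identity(self):
        arr = np.random.default_rng(0).integers(0, 65536, (16, 16)).astype(np.uint16)
        f = ImageFrame(arr)
        assert gaussian_blur(f, 0.0) is f

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(ImageFrame(np.zeros((4, 4), dtype=np.uint16)), -1)

    def test_impulse_mass_conserved(self):
        arr = np.zeros((64, 64), dtype=np.uint16)
        arr[32, 32] = 60000
        out = gaussian_blur(ImageFrame(arr), 2.0)
        assert abs(int(out.pixels.sum()) - 60000) / 60000 < 0.005


class TestSubtractBackground:
    def test_flat_frame_becomes_zero(self):
        f = ImageFrame(np.full((32, 32), 120, dtype=np.uint8), bit_depth=8)
        assert not subtract_background(f, 5).pixels.any()

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(ImageFrame(np.zeros((8, 8), dtype=np.uint16)), 0)

    def test_matches_brute_force_opening(self, rng):
        """Oracle: erosion-then-dilation with the exact disk neighborhood."""
        arr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        fp = skmorph.disk(5)
        opened = ndi.grey_dilation(ndi.grey_erosion(arr, footprint=fp), footprint=fp)
        expected = np.clip(arr.astype(int) - opened.astype(int), 0, 255)
        out = subtract_background(ImageFrame(arr, bit_depth=8), 5)
        assert np.array_equal(out.pixels, expected.astype(np.uint8))

    def test_dark_disk_survives_on_inverted_polarity_path(self):
        # bubbles darker than background: inversion makes them bright bumps
        arr = np.full((64, 64), 200, dtype=np.uint8)
        arr[disk_mask((64, 64), (32, 32), 6)] = 80
        inverted = ImageFrame(255 - arr, bit_depth=8)
        out = subtract_background(inverted, 12)
        inside = out.pixels[disk_mask((64, 64), (32, 32), 4)]
        outside = out.pixels[~disk_mask((64, 64), (32, 32), 10)]
        assert inside.min() >= 100
        assert outside.max() <= 5

    def test_gradient_flattened_under_large_radius(self):
        # opening radius 10 px >> 2 px spots; the unavoidable boundary
        # term at the bright edge of the ramp is amplitude * radius/width
        rows = np.linspace(100, 200, 256).astype(np.uint8)
        arr = np.tile(rows, (128, 1))
        spots = [(64, 60), (64, 130), (64, 200)]
        for c in spots:
            arr[disk_mask((128, 256), c, 2)] = 250
        out = subtract_background(ImageFrame(arr, bit_depth=8), 10)
        bg_mask = np.ones((128, 256), dtype=bool)
        for c in spots:
            bg_mask &= ~disk_mask((128, 256), c, 5)
        bg = out.pixels[bg_mask]
        assert int(bg.max()) - int(bg.min()) < 0.05 * 100
        for c in spots:  # spots survive the subtraction
            assert out.pixels[c] > 40


# ---------------------------------------------------------------------------
# binarize / watershed / remove_outliers
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_background_only_gives_empty_mask(self):
        f = ImageFrame(np.full((16, 16), 10, dtype=np.uint8), bit_depth=8)
        assert not binarize(f, 50, "bright").any()

    def test_disk_footprint_close_to_truth(self):
        arr = np.zeros((64, 64), dtype=np.uint8)
        truth = disk_mask((64, 64), (32, 32), 10)
        arr[truth] = 200
        mask = binarize(ImageFrame(arr, bit_depth=8), 100, "bright")
        dilated = ndi.binary_dilation(truth)
        assert (mask & ~dilated).sum() == 0
        assert np.array_equal(mask | truth, truth | mask)

    def test_polarity_inversion_symmetry(self, rng):
        arr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        f = ImageFrame(arr, bit_depth=8)
        fi = ImageFrame(255 - arr, bit_depth=8)
        assert np.array_equal(binarize(f, 90, "dark"), binarize(fi, 255 - 90, "bright"))


class TestWatershed:
    def test_empty_mask_gives_zero_labels(self):
        labels = watershed_split(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 0

    def test_single_disk_one_label(self):
        labels = watershed_split(disk_mask((64, 64), (32, 32), 12))
        assert labels.max() == 1

    def test_two_overlapping_disks_split_into_two(self):
        mask = disk_mask((80, 100), (40, 38), 15) | disk_mask((80, 100), (40, 62), 15)
        labels = watershed_split(mask)
        areas = np.bincount(labels.ravel())[1:]
        assert len(areas) == 2
        single = np.pi * 15**2
        assert all(abs(a - single) / single < 0.2 for a in areas)

    def test_never_merges_components(self, rng):
        mask = rng.random((96, 96)) < 0.4
        mask = ndi.binary_opening(mask)
        n_components = ndi.label(mask)[1]
        labels = watershed_split(mask)
        assert labels.max() >= n_components
        # and no mask pixel is dropped
        assert np.array_equal(labels > 0, mask)


class TestRemoveOutliers:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        assert not remove_outliers(mask, 2, 0.5).any()

    def test_solid_block_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        out = remove_outliers(mask, 2, 0.5)
        assert out[6:14, 6:14].all()
        assert abs(int(out.sum()) - 100) <= 8  # corners may round off

    def test_salt_noise_matches_median_oracle(self, rng):
        truth = disk_mask((100, 100), (50, 50), 20)
        noisy = truth | (rng.random((100, 100)) < 0.01)
        cleaned = remove_outliers(noisy, 2, 0.5)
        oracle = ndi.median_filter(
            noisy.astype(np.uint8), footprint=skmorph.disk(2), mode="reflect"
        ).astype(bool)
        assert np.array_equal(cleaned, oracle)
        assert abs(int(cleaned.sum()) - int(truth.sum())) / truth.sum() < 0.01
        isolated = noisy & ~ndi.binary_dilation(truth, iterations=3)
        assert not (cleaned & isolated).any()


# ---------------------------------------------------------------------------
# measure / filter
# ---------------------------------------------------------------------------

class TestMeasureParticles:
    def test_disk_geometry(self):
        labels = disk_mask((128, 128), (64, 64), 20).astype(int)
        rec = measure_particles(labels, 0.16)[0]
        assert abs(rec.equiv_radius_um - 3.2) <= 0.16
        assert rec.circularity >= 0.9
        assert rec.solidity >= 0.95
        assert not rec.on_border

    def test_ellipse_less_circular_than_disk(self):
        img = np.zeros((128, 256), dtype=int)
        rr, cc = draw_disk((64, 64), 17.3)
        img[rr, cc] = 1
        rr, cc = draw_ellipse(64, 192, 10, 30)  # 3:1 axes, same area
        img[rr, cc] = 2
        recs = {r.label: r for r in measure_particles(img, 1.0)}
        assert recs[2].circularity < recs[1].circularity

    def test_single_pixel_object(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[4, 4] = 1
        rec = measure_particles(labels, 0.5)[0]
        assert rec.area_um2 == pytest.approx(0.25)
        assert rec.circularity == 1.0

    def test_border_object_flagged(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[0:5, 10:20] = 1
        assert measure_particles(labels, 1.0)[0].on_border

    def test_empty_labels_empty_list(self):
        assert measure_particles(np.zeros((8, 8), dtype=int), 1.0) == []

    def test_circularity_converges_to_one_with_radius(self):
        # half-integer radii avoid Pythagorean lattice bumps on the rim;
        # the Crofton estimator oscillates around 1, so convergence is
        # checked on the unclamped ratio at the endpoints
        devs = {}
        for r in (5.5, 10.5, 20.5, 40.5):
            labels = disk_mask((128, 128), (64, 64), r).astype(int)
            rec = measure_particles(labels, 1.0)[0]
            assert rec.circularity > 0.99
            devs[r] = abs(1.0 - 4 * np.pi * rec.area_um2 / rec.perimeter_um**2)
        assert devs[40.5] <= devs[5.5]


class TestFilterParticles:
    @staticmethod
    def _panel():
        img = np.zeros((256, 1024), dtype=int)
        label = 0
        for i in range(30):
            label += 1
            rr, cc = draw_disk((64 + 110 * (i // 15), 30 + 66 * (i % 15)), 12)
            img[rr, cc] = label
        for i in range(10):
            label += 1
            rr, cc = draw_ellipse(200, 50 + 95 * i, 7, 21)
            img[rr, cc] = label
        return measure_particles(img, 1.0)

    def test_permissive_criteria_is_identity(self):
        recs = self._panel()
        assert filter_particles(recs, FilterCriteria()) == recs

    def test_circularity_filter_separates_disks_from_ellipses(self):
        recs = self._panel()
        kept = filter_particles(recs, FilterCriteria(circularity_min=0.8))
        assert len(kept) == 30
        assert all(r.label <= 30 for r in kept)

    def test_empty_input(self):
        assert filter_particles([], FilterCriteria(circularity_min=0.5)) == []

    def test_order_independent(self, rng):
        recs = self._panel()
        crit = FilterCriteria(circularity_min=0.8, solidity_min=0.9)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        a = {r.label for r in filter_particles(recs, crit)}
        b = {r.label for r in filter_particles(shuffled, crit)}
        assert a == b

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(circularity_min=0.9, circularity_max=0.1)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

class TestSegmentImage:
    def test_blank_frame_yields_no_records(self):
        f = ImageFrame(np.full((128, 128), 40000, dtype=np.uint16), pixel_size_um=0.16)
        assert segment_image(f, SegmentationParams()) == []

    def test_uncalibrated_frame_rejected_with_stage_name(self):
        f = ImageFrame(np.zeros((64, 64), dtype=np.uint16))
        with pytest.raises(SegmentationError, match="calibration"):
            segment_image(f)

    def test_deterministic_reruns(self):
        from bubblekit import BrightfieldSpec, render_brightfield

        frame, _ = render_brightfield(
            BrightfieldSpec(field_of_view_px=(256, 256), target_count_per_image=8, seed=5)
        )
        a = segment_image(frame, SegmentationParams())
        b = segment_image(frame, SegmentationParams())
        assert a == b
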