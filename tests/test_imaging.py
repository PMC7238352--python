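"""ROI cropping, histogram equalization, region growing and contour tracing."""

import numpy as np
import pytest
from scipy import ndimage

from birads_cad.imaging import (
    Contour,
    MassMask,
    ROIImage,
    crop_roi,
    equalize_histogram,
    extract_contour,
    fill_holes,
    generate_candidates,
    region_grow,
    select_candidate,
)


def brute_force_flood(pixels, seed, threshold):
    """Independent 8-connected flood fill by explicit BFS."""
    grid = np.asarray(pixels)
    mask = np.zeros(grid.shape, dtype=bool)
    if grid[seed] < threshold:
        mask[seed] = True
        return mask
    stack = [seed]
    mask[seed] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < grid.shape[0]
                    and 0 <= cc < grid.shape[1]
                    and not mask[rr, cc]
                    and grid[rr, cc] >= threshold
                ):
                    mask[rr, cc] = True
                    stack.append((rr, cc))
    return mask


class TestCropROI:
    def test_full_window_is_identity(self):
        image = np.arange(81).reshape(9, 9) % 256
        roi = crop_roi(image, (4, 4), 4)
        np.testing.assert_array_equal(roi.pixels, image)

    def test_interior_window_indices(self):
        image = np.arange(100).reshape(10, 10)
        roi = crop_roi(image, (5, 5), 2)
        np.testing.assert_array_equal(roi.pixels, image[3:8, 3:8])

    def test_corner_window_is_clamped(self):
        image = np.arange(100).reshape(10, 10)
        roi = crop_roi(image, (0, 0), 2)
        assert roi.pixels.shape == (3, 3)
        np.testing.assert_array_equal(roi.pixels, image[0:3, 0:3])

    def test_center_outside_raises(self):
        with pytest.raises(ValueError):
            crop_roi(np.zeros((5, 5)), (7, 2), 2)


class TestHistogramEqualization:
    def test_constant_image_stays_constant(self):
        roi = ROIImage(np.full((6, 6), 17))
        out = equalize_histogram(roi)
        assert len(np.unique(out.pixels)) == 1

    def test_uniform_histogram_is_fixed_point(self):
        image = np.arange(256).reshape(16, 16)
        out = equalize_histogram(ROIImage(image))
        assert np.max(np.abs(out.pixels - image)) <= 1

    def test_matches_hand_computed_cdf(self):
        # 3x3 toy: five 10s, three 20s, one 30 -> round(255 * CDF)
        image = np.array([[10, 10, 10], [10, 10, 20], [20, 20, 30]])
        out = equalize_histogram(ROIImage(image))
        expected = {10: round(255 * 5 / 9), 20: round(255 * 8 / 9), 30: 255}
        for level, mapped in expected.items():
            assert (out.pixels[image == level] == mapped).all()

    def test_mapping_is_monotone(self, rng):
        image = rng.integers(0, 256, size=(24, 24))
        out = equalize_histogram(ROIImage(image)).pixels
        flat_in, flat_out = image.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()


class TestRegionGrow:
    def test_uniform_image_grows_everywhere(self):
        roi = ROIImage(np.full((7, 7), 120))
        assert region_grow(roi, 100).mask.all()

    def test_threshold_above_maximum_keeps_seed_only(self):
        roi = ROIImage(np.full((7, 7), 120))
        mask = region_grow(roi, 200)
        assert mask.area_px == 1 and mask.mask[3, 3]

    def test_matches_brute_force_flood_fill(self, rng):
        pixels = np.full((8, 8), 50)
        pixels[3:6, 3:6] = 200
        roi = ROIImage(pixels)
        grown = region_grow(roi, 100)
        expected = brute_force_flood(pixels, roi.center, 100)
        np.testing.assert_array_equal(grown.mask, expected)
        # and on a batch of random images at random thresholds
        for _ in range(20):
            pix = rng.integers(0, 256, size=(11, 11))
            thr = float(rng.integers(0, 256))
            got = region_grow(ROIImage(pix), thr).mask
            np.testing.assert_array_equal(got, brute_force_flood(pix, (5, 5), thr))

    def test_masks_are_connected_and_contain_seed(self, rng):
        for _ in range(10):
            pix = rng.integers(0, 256, size=(15, 15))
            mask = region_grow(ROIImage(pix), 128)
            assert mask.mask[mask.seed]
            _, n = ndimage.label(mask.mask, structure=np.ones((3, 3)))
            assert n == 1


class TestCandidates:
    def test_count_matches_requested_thresholds(self, ideal_disc):
        roi, _, _ = ideal_disc
        assert len(generate_candidates(roi, 7)) == 7

    def test_single_threshold_is_midpoint(self):
        pixels = np.full((9, 9), 10)
        pixels[3:6, 3:6] = 200
        cands = generate_candidates(ROIImage(pixels), 1)
        # midpoint threshold 105 keeps exactly the bright block
        assert len(cands) == 1 and cands[0].area_px == 9

    def test_nesting_of_adjacent_thresholds(self, rng):
        pix = rng.integers(0, 256, size=(21, 21))
        pix[10, 10] = 255  # keep the seed pixel in every candidate
        cands = generate_candidates(ROIImage(pix), 9)
        for bigger, smaller in zip(cands, cands[1:]):
            assert (smaller.mask <= bigger.mask).all()

    def test_constant_roi_yields_single_candidate(self, caplog):
        with caplog.at_level("WARNING"):
            cands = generate_candidates(ROIImage(np.full((5, 5), 9)), 5)
        assert len(cands) == 1


class TestSelectCandidate:
    def test_single_candidate_returned(self):
        m = MassMask(np.ones((3, 3), bool), seed=(1, 1))
        assert select_candidate([m], target_radius=5.0) is m

    def test_equivalent_radius_arithmetic(self):
        small = np.zeros((40, 40), bool)
        small[14:24, 15:25] = True  # 100 px -> r ~ 5.6
        big = np.zeros((40, 40), bool)
        big[9:29, 9:29] = True  # 400 px -> r ~ 11.3
        cands = [MassMask(small, seed=(18, 18)), MassMask(big, seed=(18, 18))]
        assert select_candidate(cands, target_radius=11.0).area_px == 400

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            select_candidate([], target_radius=3.0)

    def test_candidate_gallery_written(self, tmp_path, ideal_disc):
        from birads_cad.imaging import write_candidate_gallery

        roi, _, _ = ideal_disc
        cands = generate_candidates(roi, 4)
        paths = write_candidate_gallery(str(tmp_path), cands)
        assert len(paths) == 4
        assert all(p.endswith(".png") for p in paths)

    def test_interactive_uses_chooser(self):
        masks = [MassMask(np.ones((2, 2), bool), seed=(0, 0)) for _ in range(3)]
        chosen = select_candidate(masks, strategy="interactive", chooser=lambda c: 2)
        assert chosen is masks[2]

    def test_recovers_disc_phantom(self, ideal_disc):
        roi, truth, meta = ideal_disc
        cands = generate_candidates(roi, 16)
        best = select_candidate(cands, target_radius=meta["approx_radius_px"])
        inter = np.logical_and(best.mask, truth.mask).sum()
        dice = 2 * inter / (best.mask.sum() + truth.mask.sum())
        assert dice >= 0.95


class TestContour:
    def test_single_pixel_mask(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert extract_contour(m).points == [(1, 1)]

    def test_filled_square_clockwise(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        expected = [(1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1)]
        assert extract_contour(m).points == expected

    def test_disc_contour_length_near_circumference(self):
        rr, cc = np.meshgrid(np.arange(13), np.arange(13), indexing="ij")
        disc = (rr - 6) ** 2 + (cc - 6) ** 2 <= 25
        contour = extract_contour(disc)
        circumference = 2 * np.pi * 5
        assert abs(len(contour) - circumference) <= 0.2 * circumference
        # closed loop: last point is a neighbour of the first
        first, last = contour.points[0], contour.points[-1]
        assert max(abs(first[0] - last[0]), abs(first[1] - last[1])) == 1

    def test_round_trip_recovers_simply_connected_masks(
        self, ideal_disc, spiculated_phantom
    ):
        for _, mask, _ in (ideal_disc, spiculated_phantom):
            filled = fill_holes(mask)
            recovered = extract_contour(filled).to_mask(filled.mask.shape)
            np.testing.assert_array_equal(recovered, filled.mask)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((4, 4), bool))
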