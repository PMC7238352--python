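"""Shape descriptors: boundary geometry, convex-hull difference, variation."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from birads_cad.imaging import extract_contour
from birads_cad.shape_features import (
    VariationProfile,
    boundary_geometry,
    difference_area,
    shape_features,
    variation_profile,
    variation_stats,
)
from birads_cad.synthfix import PhantomSpec, make_phantom


def oracle_hull_pixel_count(mask):
    """Independent point-in-hull count via Delaunay triangulation."""
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] < 3:
        return pts.shape[0]
    try:
        tri = Delaunay(pts)
    except Exception:
        return pts.shape[0]
    r0, c0 = pts.min(axis=0).astype(int)
    r1, c1 = pts.max(axis=0).astype(int)
    count = 0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if tri.find_simplex((r, c)) >= 0:
                count += 1
    return count


def oracle_feret(mask, angles):
    """Brute-force pairwise-projection Feret extent."""
    pts = np.argwhere(mask).astype(float)
    xy = np.column_stack([pts[:, 1], pts[:, 0]])
    out = []
    for phi in angles:
        u = np.array([np.cos(phi), np.sin(phi)])
        proj = xy @ u
        out.append(proj.max() - proj.min())
    return np.array(out)


def digital_disc(radius, pad=3):
    side = 2 * (radius + pad) + 1
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    c = side // 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


class TestBoundaryGeometry:
    def test_straight_segment_has_no_curvature(self):
        pts = np.column_stack([np.zeros(50), np.linspace(0, 40, 50)])
        continuity, curvature, irregularity = boundary_geometry(pts, closed=False)
        assert curvature == pytest.approx(0.0, abs=1e-12)
        assert irregularity == 0

    def test_square_boundary_has_four_direction_changes(self):
        m = np.zeros((44, 44), bool)
        m[2:42, 2:42] = True
        contour = extract_contour(m)
        _, _, irregularity = boundary_geometry(contour, n_points=8)
        assert irregularity == 4

    def test_irregularity_monotone_in_boundary_amplitude(self):
        values = []
        for amp in (0.0, 2.0, 4.0):
            _, mask, _ = make_phantom(
                PhantomSpec(
                    category="B4",
                    radius_px=20,
                    amplitude=amp,
                    harmonics=(5, 7),
                    edge_blur_sigma=0.0,
                    noise_sigma=0.0,
                    seed=5,
                )
            )
            _, _, irr = boundary_geometry(extract_contour(mask))
            values.append(irr)
        assert values[0] <= values[1] <= values[2]

    def test_degenerate_contour_raises(self):
        with pytest.raises(ValueError):
            boundary_geometry(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestDifferenceArea:
    def test_convex_regions_have_zero_difference(self):
        square = np.zeros((10, 10), bool)
        square[2:8, 2:8] = True
        assert difference_area(square) == 0
        assert difference_area(digital_disc(7)) == 0

    @pytest.mark.parametrize("case", ["plus", "crescent", "blob"])
    def test_matches_exhaustive_hull_oracle(self, case, rng):
        if case == "plus":
            m = np.zeros((7, 7), bool)
            m[2:5, 1:6] = True
            m[1, 3] = m[5, 3] = True  # 17-px thick plus
        elif case == "crescent":
            disc = digital_disc(8)
            bite = np.roll(digital_disc(8), 6, axis=1)
            m = disc & ~bite
        else:
            m = np.zeros((15, 15), bool)
            m[np.unravel_index(rng.choice(225, 40, replace=False), (15, 15))] = True
        expected = oracle_hull_pixel_count(m) - int(m.sum())
        assert difference_area(m) == expected

    def test_crescent_is_strictly_concave(self):
        disc = digital_disc(8)
        m = disc & ~np.roll(disc, 6, axis=1)
        assert difference_area(m) > 0


class TestVariationProfile:
    def test_disc_extent_is_diameter_at_every_angle(self):
        prof = variation_profile(digital_disc(10))
        assert np.all(np.abs(prof.extent - 20.0) <= 1.0)

    def test_two_pixel_projection_geometry(self):
        m = np.zeros((3, 12), bool)
        m[0, 0] = m[0, 10] = True
        prof = variation_profile(m, n_angles=180)
        assert prof.extent[0] == pytest.approx(10.0)
        assert prof.extent[90] == pytest.approx(0.0, abs=1e-9)

    def test_ellipse_extremes(self):
        rr, cc = np.meshgrid(np.arange(51), np.arange(51), indexing="ij")
        ell = ((cc - 25) / 20.0) ** 2 + ((rr - 25) / 10.0) ** 2 <= 1.0
        prof = variation_profile(ell)
        assert prof.extent.max() == pytest.approx(40.0, abs=1.5)
        assert prof.extent.min() == pytest.approx(20.0, abs=1.5)

    def test_matches_brute_force_pairwise_oracle(self, rng):
        m = np.zeros((12, 12), bool)
        m[np.unravel_index(rng.choice(144, 25, replace=False), (12, 12))] = True
        angles = np.arange(16) * np.pi / 16
        got = variation_profile(m, n_angles=16).extent
        np.testing.assert_allclose(got, oracle_feret(m, angles), atol=1e-9)

    def test_single_pixel_mask_warns_and_zeroes(self, caplog):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with caplog.at_level("WARNING"):
            prof = variation_profile(m)
        assert not prof.extent.any()


class TestVariationStats:
    def test_constant_profile(self):
        prof = VariationProfile(np.arange(8.0), np.full(8, 3.0))
        mean, var, skew, kurt, entropy = variation_stats(prof)
        assert (mean, var, skew, kurt) == (3.0, 0.0, 0.0, 0.0)
        assert entropy == pytest.approx(np.log2(8))

    def test_two_point_arithmetic(self):
        prof = VariationProfile(np.array([0.0, 1.0]), np.array([1.0, 3.0]))
        mean, var, *_ = variation_stats(prof)
        assert (mean, var) == (2.0, 1.0)

    def test_disc_flat_ellipse_varied(self):
        disc_var = variation_stats(variation_profile(digital_disc(10)))[1]
        rr, cc = np.meshgrid(np.arange(51), np.arange(51), indexing="ij")
        ell = ((cc - 25) / 20.0) ** 2 + ((rr - 25) / 10.0) ** 2 <= 1.0
        ell_var = variation_stats(variation_profile(ell))[1]
        assert disc_var < 1.0 < ell_var


class TestShapeFeatures:
    def test_nine_finite_values(self, ideal_disc, ideal_disc_contour):
        _, mask, _ = ideal_disc
        values = shape_features(mask, ideal_disc_contour).as_array()
        assert values.shape == (9,) and np.isfinite(values).all()

    def test_disc_is_convex_and_isotropic(self, ideal_disc, ideal_disc_contour):
        _, mask, _ = ideal_disc
        feats = shape_features(mask, ideal_disc_contour)
        assert feats.difference_area == 0
        assert feats.variance_variation < 1.0

    def test_spiculated_more_irregular_than_disc(
        self, ideal_disc, ideal_disc_contour, spiculated_phantom
    ):
        _, disc_mask, _ = ideal_disc
        _, spic_mask, _ = spiculated_phantom
        disc = shape_features(disc_mask, ideal_disc_contour)
        spic = shape_features(spic_mask)
        assert spic.irregularity > disc.irregularity

    def test_rotation_changes_mean_variation_little(self, spiculated_phantom):
        _, mask, _ = spiculated_phantom
        base = variation_stats(variation_profile(mask.mask))[0]
        rotated = variation_stats(variation_profile(np.rot90(mask.mask)))[0]
        assert abs(rotated - base) / base < 0.02
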