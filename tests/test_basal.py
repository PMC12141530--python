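"""Depth field, binning, and basal-fraction behavior against oracles."""

import numpy as np
import pytest

from epiquant import (
    LayerSegmentation,
    basal_mrna_fraction,
    bin_intensity_profile,
    compute_depth_field,
    generate_layer_section,
    subtract_background,
)


def brute_force_profile(intensity, mask, n_bins=10):
    """Independent accumulation using row-fraction depth on a rectangle."""
    rows = np.nonzero(mask.any(axis=1))[0]
    r0, r1 = rows[0], rows[-1]
    sums = np.zeros(n_bins)
    total = 0.0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                u = (r - r0) / (r1 - r0)
                b = min(int(u * n_bins), n_bins - 1)
                sums[b] += intensity[r, c]
                total += intensity[r, c]
    return sums / total


class TestDepthField:
    def test_rectangle_row_fraction(self, rect_layer):
        u = compute_depth_field(rect_layer).u
        assert u[30, 60] == pytest.approx(30 / 99, abs=1e-9)

    def test_midpoint_is_half(self, rect_layer):
        # 100 rows: rows 49 and 50 straddle the midline symmetrically
        u = compute_depth_field(rect_layer).u
        assert (u[49, 60] + u[50, 60]) / 2 == pytest.approx(0.5, abs=1e-9)

    def test_boundary_pixels_near_extremes(self, rect_layer):
        u = compute_depth_field(rect_layer).u
        assert u[0].max() <= 0.05 and u[-1].min() >= 0.95

    def test_curved_band_matches_analytic_normal_offset(self):
        _, layer, gt = generate_layer_section(
            shape=(160, 256), layer_geometry="curved", n_spots=0, seed=0
        )
        u = compute_depth_field(layer).u
        analytic = gt.extras["analytic_depth"]
        rms = np.sqrt(np.nanmean((u[layer.mask] - analytic[layer.mask]) ** 2))
        assert rms < 0.02

    def test_touching_boundaries_error(self):
        # geometrically distinct parallel lines that rasterize to one row
        layer = LayerSegmentation(
            mask=np.ones((5, 10), dtype=bool),
            basal_boundary=np.array([[0.0, 2.2], [9.0, 2.2]]),
            apical_boundary=np.array([[0.0, 2.4], [9.0, 2.4]]),
        )
        with pytest.raises(ValueError, match="touch"):
            compute_depth_field(layer)


class TestBackground:
    def test_scalar_subtraction(self, rect_layer):
        out = subtract_background(
            np.full(rect_layer.mask.shape, 5.0), rect_layer.mask, 2.0
        )
        assert np.all(out[rect_layer.mask] == 3.0)

    def test_oversubtraction_clamps_then_binning_raises(self, rect_layer):
        out = subtract_background(
            np.full(rect_layer.mask.shape, 5.0), rect_layer.mask, 10.0
        )
        assert out.max() == 0.0
        depth = compute_depth_field(rect_layer)
        with pytest.raises(ValueError, match="zero total intensity"):
            bin_intensity_profile(out, depth)

    def test_auto_uses_outside_median(self):
        img = np.full((40, 40), 10.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        img[mask] = 100.0
        out = subtract_background(img, mask, "auto")
        assert np.all(out[mask] == 90.0)

    def test_auto_without_outside_pixels_errors(self):
        mask = np.ones((10, 10), dtype=bool)
        with pytest.raises(ValueError, match="non-mask"):
            subtract_background(np.ones((10, 10)), mask, "auto")


class TestBinningAndFraction:
    def test_uniform_intensity_equal_bins(self, rect_layer):
        depth = compute_depth_field(rect_layer)
        prof = bin_intensity_profile(rect_layer.mask.astype(float), depth)
        np.testing.assert_allclose(prof.fractions, 0.1, atol=0.01)
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_basal_stripe_all_in_first_bin(self, rect_layer):
        intensity = np.zeros(rect_layer.mask.shape)
        intensity[0:5] = 1.0
        depth = compute_depth_field(rect_layer)
        prof = bin_intensity_profile(intensity, depth)
        assert prof.fractions[0] == pytest.approx(1.0)
        assert basal_mrna_fraction(prof) == pytest.approx(1.0)

    def test_exponential_profile_matches_closed_form(self):
        from epiquant import expected_bin_fractions

        image, layer, gt = generate_layer_section(
            shape=(260, 220), depth_law="exponential", tau=0.2,
            n_spots=100000, noise_sd=0.0, seed=2,
        )
        depth = compute_depth_field(layer)
        prof = bin_intensity_profile(image.channel("rna"), depth)
        closed = expected_bin_fractions("exponential", 10, tau=0.2)
        np.testing.assert_allclose(prof.fractions, closed, atol=0.01)

    def test_linear_density_closed_form(self):
        """f(u) = 2(1-u): integral over [0, 0.3] is 0.51."""
        h, w = 200, 60
        mask = np.ones((h, w), dtype=bool)
        layer = LayerSegmentation(
            mask,
            np.array([[0.0, 0.0], [w - 1.0, 0.0]]),
            np.array([[0.0, h - 1.0], [w - 1.0, h - 1.0]]),
        )
        depth = compute_depth_field(layer)
        intensity = 2.0 * (1.0 - depth.u)
        intensity[~mask] = 0.0
        prof = bin_intensity_profile(intensity, depth)
        assert basal_mrna_fraction(prof) == pytest.approx(0.51, abs=0.005)

    def test_misaligned_cutoff_rejected(self, rect_layer):
        depth = compute_depth_field(rect_layer)
        prof = bin_intensity_profile(rect_layer.mask.astype(float), depth)
        with pytest.raises(ValueError, match="multiple"):
            basal_mrna_fraction(prof, basal_cutoff=0.25)


class TestInvariances:
    def test_intensity_scale_invariance(self):
        image, layer, _ = generate_layer_section(n_spots=2000, seed=4)
        depth = compute_depth_field(layer)
        rna = image.channel("rna")
        f1 = basal_mrna_fraction(bin_intensity_profile(rna, depth))
        f2 = basal_mrna_fraction(bin_intensity_profile(rna * 37.5, depth))
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(5)
        h, w = 60, 40
        mask = np.ones((h, w), dtype=bool)
        layer = LayerSegmentation(
            mask,
            np.array([[0.0, 0.0], [w - 1.0, 0.0]]),
            np.array([[0.0, h - 1.0], [w - 1.0, h - 1.0]]),
        )
        intensity = rng.uniform(0, 10, (h, w))
        depth = compute_depth_field(layer)
        prof = bin_intensity_profile(intensity, depth)
        np.testing.assert_allclose(
            prof.fractions, brute_force_profile(intensity, mask), atol=1e-9
        )

    def test_translation_invariance_exact(self):
        image, layer, _ = generate_layer_section(
            shape=(120, 160), n_spots=1000, seed=6
        )
        rna = image.channel("rna")
        depth = compute_depth_field(layer)
        f1 = basal_mrna_fraction(bin_intensity_profile(rna, depth))

        pad = 17
        big = np.zeros((120 + pad, 160 + pad))
        big[pad:, pad:] = rna
        mask2 = np.zeros_like(big, dtype=bool)
        mask2[pad:, pad:] = layer.mask
        layer2 = LayerSegmentation(
            mask2,
            layer.basal_boundary + pad,
            layer.apical_boundary + pad,
        )
        f2 = basal_mrna_fraction(bin_intensity_profile(big, compute_depth_field(layer2)))
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_rotation_90_invariance_exact(self):
        image, layer, _ = generate_layer_section(n_spots=1000, seed=7)
        rna = image.channel("rna")
        depth = compute_depth_field(layer)
        f1 = basal_mrna_fraction(bin_intensity_profile(rna, depth))
        # rotate everything 90 degrees counterclockwise
        rot = np.rot90(rna)
        mask_r = np.rot90(layer.mask)
        h = rna.shape[0]

        def rot_poly(p):
            return np.column_stack([p[:, 1], rna.shape[1] - 1 - p[:, 0]])

        layer_r = LayerSegmentation(
            mask_r, rot_poly(layer.basal_boundary), rot_poly(layer.apical_boundary)
        )
        f2 = basal_mrna_fraction(bin_intensity_profile(rot, compute_depth_field(layer_r)))
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_tau_monotonicity(self):
        from epiquant import expected_basal_fraction

        measured = []
        for tau in (0.1, 0.2, 0.5, 1.0, 5.0):
            image, layer, _ = generate_layer_section(
                shape=(260, 220), depth_law="exponential", tau=tau,
                n_spots=100000, seed=8,
            )
            depth = compute_depth_field(layer)
            bf = basal_mrna_fraction(
                bin_intensity_profile(image.channel("rna"), depth)
            )
            expected = expected_basal_fraction("exponential", tau=tau).value
            assert bf == pytest.approx(expected, abs=0.01)
            measured.append(bf)
        assert all(a > b for a, b in zip(measured, measured[1:]))
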