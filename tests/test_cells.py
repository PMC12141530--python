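"""Cortical ratio and PDI against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from epiquant import (
    CellRegion,
    batch_cell_metrics,
    cortical_ratio,
    generate_cell,
    pdi,
    radial_zones,
)


def brute_force_cortical(mask, intensity, peripheral=0.15, central=0.65):
    """Independent per-pixel implementation via explicit distance minimization."""
    ys, xs = np.nonzero(mask)
    bys, bxs = np.nonzero(~mask)
    d = cdist(np.c_[ys, xs], np.c_[bys, bxs]).min(axis=1)
    r = 1.0 - d / d.max()
    vals = intensity[ys, xs]
    return vals[r >= 1 - peripheral].mean() / vals[r <= central].mean()


def brute_force_pdi(mask, intensity):
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    w = intensity[ys, xs]
    r2 = (ys - cy) ** 2 + (xs - cx) ** 2
    return ((w * r2).sum() / w.sum()) / r2.mean()


class TestCorticalRatio:
    def test_uniform_is_one(self, disk_cell):
        cell, _ = disk_cell
        assert cortical_ratio(cell, cell.mask.astype(float)) == pytest.approx(1.0)

    def test_two_zone_recovers_contrast(self):
        image, cell, gt = generate_cell(radius_px=40, profile="two_zone",
                                        contrast=3.0, seed=0)
        assert cortical_ratio(cell, image.channel("signal")) == pytest.approx(
            3.0, abs=0.05
        )

    def test_radial_profile_closed_form(self):
        # intensity ~ normalized radius: area-weighted zone means give ~2.14
        image, cell, gt = generate_cell(radius_px=40, profile="radial_power",
                                        power=1.0, seed=0)
        measured = cortical_ratio(cell, image.channel("signal"))
        assert measured == pytest.approx(gt.expected["cortical_ratio"].value,
                                         rel=0.02)

    def test_brute_force_oracle_equivalence(self):
        image, cell, _ = generate_cell(radius_px=22, profile="radial_power",
                                       power=1.0, margin=5, seed=0)
        ch = image.channel("signal")
        assert cortical_ratio(cell, ch) == pytest.approx(
            brute_force_cortical(cell.mask, ch), abs=1e-9
        )

    def test_degenerate_central_signal(self, disk_cell):
        cell, (c, r) = disk_cell
        intensity = np.zeros(cell.mask.shape)
        zones = radial_zones(cell)
        intensity[zones.peripheral] = 1.0
        with pytest.raises(ValueError, match="degenerate central"):
            cortical_ratio(cell, intensity)

    def test_monotone_in_contrast(self):
        values = []
        for c in (1.0, 2.0, 4.0):
            image, cell, _ = generate_cell(radius_px=30, profile="two_zone",
                                           contrast=c, seed=0)
            values.append(cortical_ratio(cell, image.channel("signal")))
        assert values[0] < values[1] < values[2]

    def test_area_mode_zone_fractions(self, disk_cell):
        cell, _ = disk_cell
        zones = radial_zones(cell, mode="area")
        n = cell.mask.sum()
        assert zones.peripheral.sum() / n == pytest.approx(0.15, abs=0.02)
        assert zones.central.sum() / n == pytest.approx(0.65, abs=0.02)


class TestPdi:
    def test_uniform_is_exactly_one(self, disk_cell):
        cell, _ = disk_cell
        assert pdi(cell, cell.mask.astype(float)) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_on_irregular_mask_is_one(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 15:40] = True
        mask[20:30, 40:55] = True  # non-convex blob
        cell = CellRegion(mask, "blob")
        assert pdi(cell, mask.astype(float)) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_at_centroid_near_zero(self, disk_cell):
        cell, (c, r) = disk_cell
        intensity = np.zeros(cell.mask.shape)
        intensity[c, c] = 100.0
        assert pdi(cell, intensity) == pytest.approx(0.0, abs=1e-6)

    def test_rim_concentration_near_two(self, disk_cell):
        cell, (c, r) = disk_cell
        yy, xx = np.mgrid[0 : cell.mask.shape[0], 0 : cell.mask.shape[1]]
        rho = np.hypot(yy - c, xx - c)
        intensity = (cell.mask & (rho >= r - 1)).astype(float)
        assert pdi(cell, intensity) == pytest.approx(2.0, rel=0.05)

    def test_radial_profile_moment_ratio(self):
        image, cell, gt = generate_cell(radius_px=40, profile="radial_power",
                                        power=1.0, seed=0)
        assert pdi(cell, image.channel("signal")) == pytest.approx(1.2, abs=0.01)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((48, 48), dtype=bool)
        mask[8:40, 10:38] = True
        cell = CellRegion(mask, "rect")
        intensity = rng.uniform(0, 5, mask.shape)
        assert pdi(cell, intensity) == pytest.approx(
            brute_force_pdi(mask, intensity), abs=1e-9
        )

    def test_zero_intensity_error(self, disk_cell):
        cell, _ = disk_cell
        with pytest.raises(ValueError, match="zero total"):
            pdi(cell, np.zeros(cell.mask.shape))

    def test_rim_weight_monotonicity(self, disk_cell):
        cell, (c, r) = disk_cell
        yy, xx = np.mgrid[0 : cell.mask.shape[0], 0 : cell.mask.shape[1]]
        rim = (cell.mask & (np.hypot(yy - c, xx - c) >= r - 1)).astype(float)
        uniform = cell.mask.astype(float)
        values = [
            pdi(cell, (1 - w) * uniform + w * rim) for w in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestInvariances:
    def test_intensity_scaling(self, disk_cell):
        cell, (c, r) = disk_cell
        rng = np.random.default_rng(5)
        intensity = rng.uniform(0.1, 5, cell.mask.shape)
        for fn in (cortical_ratio, pdi):
            assert fn(cell, intensity) == pytest.approx(
                fn(cell, intensity * 123.4), abs=1e-9
            )

    def test_rigid_translation_exact(self):
        image, cell, _ = generate_cell(radius_px=25, profile="radial_power",
                                       power=2.0, seed=1)
        ch = image.channel("signal")
        shifted = np.roll(np.roll(ch, 7, axis=0), -4, axis=1)
        cell2 = CellRegion(np.roll(np.roll(cell.mask, 7, axis=0), -4, axis=1),
                           "shifted")
        for fn in (cortical_ratio, pdi):
            assert fn(cell, ch) == pytest.approx(fn(cell2, shifted), abs=1e-9)

    def test_pdi_rotation_on_disk_within_1pct(self):
        image, cell, _ = generate_cell(radius_px=30, profile="radial_power",
                                       power=1.0, seed=2)
        ch = image.channel("signal")
        v0 = pdi(cell, ch)
        v90 = pdi(CellRegion(np.rot90(cell.mask), "rot"), np.rot90(ch))
        assert v90 == pytest.approx(v0, rel=0.01)


class TestBatch:
    def make_cells(self, n=3):
        out = []
        for i in range(n):
            image, cell, _ = generate_cell(radius_px=25, profile="uniform",
                                           seed=i)
            out.append((image, CellRegion(cell.mask, f"cell{i}")))
        return out

    def test_three_valid_cells_three_rows(self):
        pairs = self.make_cells()
        image = pairs[0][0]
        table = batch_cell_metrics([c for _, c in pairs], image, "signal", "pdi")
        assert len(table.rows) == 3
        assert len(table.values) == 3

    def test_failed_cell_flagged_not_fatal(self):
        pairs = self.make_cells()
        image = pairs[0][0]
        zero_image = type(image)(
            np.zeros_like(image.data), image.channels, image.pixel_size_um
        )
        cells_list = [c for _, c in pairs]
        # run against an image whose intensity is zero: all flagged
        table = batch_cell_metrics(cells_list, zero_image, "signal", "pdi")
        assert len(table.rows) == 3 and len(table.values) == 0
        ok_table = batch_cell_metrics(cells_list, image, "signal", "pdi")
        assert len(ok_table.values) == 3

    def test_determinism(self):
        pairs = self.make_cells()
        image = pairs[0][0]
        cells_list = [c for _, c in pairs]
        t1 = batch_cell_metrics(cells_list, image, "signal", "cortical_ratio")
        t2 = batch_cell_metrics(cells_list, image, "signal", "cortical_ratio")
        assert t1.rows == t2.rows
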