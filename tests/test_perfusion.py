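"""FAZ morphometry and perfusion/vessel density tests with independent oracles."""

import numpy as np
import pytest
from skimage.draw import disk

from octaquant import perfusion, vessels
from octaquant.perfusion import (
    circularity_from,
    define_region,
    faz_metrics,
    layer_metrics,
    perfusion_density,
    vessel_density,
)
from octaquant.vessels import SkeletonMap, VesselMask, restrict_skeleton, skeletonize_mask

SCALE = 5.859  # um/px


def _disc_mask(r_px: int, pad: int = 10) -> np.ndarray:
    m = np.zeros((2 * r_px + 2 * pad, 2 * r_px + 2 * pad), bool)
    rr, cc = disk((r_px + pad, r_px + pad), r_px)
    m[rr, cc] = True
    return m


class TestCircularityFormula:
    def test_circle_identity(self):
        r = 0.3
        assert circularity_from(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)
        assert circularity_from(np.pi * r**2, 2 * np.pi * r,
                                "inverse") == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 0.7
        assert circularity_from(s**2, 4 * s) == pytest.approx(np.pi / 4)
        assert circularity_from(s**2, 4 * s, "inverse") == pytest.approx(4 / np.pi)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            circularity_from(1.0, 1.0, "other")


class TestFAZMetrics:
    @pytest.mark.parametrize("r_px", [50, 80])
    def test_rasterized_disc(self, r_px):
        g = faz_metrics(_disc_mask(r_px), SCALE)
        analytic_area = np.pi * (r_px * SCALE / 1000) ** 2
        assert g.area_mm2 == pytest.approx(analytic_area, rel=0.02)
        assert 0.95 <= g.circularity <= 1.02

    def test_inverse_convention_is_reciprocal(self):
        mask = _disc_mask(60)
        lit = faz_metrics(mask, SCALE, "literal")
        inv = faz_metrics(mask, SCALE, "inverse")
        assert inv.circularity == pytest.approx(1.0 / lit.circularity)

    def test_synthetic_faz_matches_parametric_truth(self, default_slab):
        img, truth = default_slab
        g = faz_metrics(truth.faz_mask_true, img.scale_um_per_px)
        assert g.area_mm2 == pytest.approx(truth.faz_area_true, rel=0.02)
        assert g.perimeter_mm == pytest.approx(truth.faz_perimeter_true, rel=0.03)

    def test_empty_and_fragmented_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            faz_metrics(np.zeros((20, 20), bool), SCALE)
        two = np.zeros((30, 30), bool)
        two[2:5, 2:5] = True
        two[20:23, 20:23] = True
        with pytest.raises(ValueError, match="one connected component"):
            faz_metrics(two, SCALE)

    def test_isoperimetric_bound_on_random_blobs(self, rng):
        # literal circularity can never meaningfully exceed 1
        from scipy import ndimage as ndi

        for _ in range(10):
            seed_mask = rng.random((80, 80)) < 0.01
            blob = ndi.binary_dilation(seed_mask, iterations=int(rng.integers(3, 8)))
            lab, n = ndi.label(blob)
            largest = (lab == (np.bincount(lab.ravel())[1:].argmax() + 1))
            largest = ndi.binary_fill_holes(largest)
            g = faz_metrics(largest, SCALE)
            assert g.circularity <= 1.02


class TestRegion:
    def test_full_field_default(self):
        faz = _disc_mask(20, pad=50)
        region = define_region(faz, SCALE)
        np.testing.assert_array_equal(region.mask, ~faz)
        assert region.kind == "full_field_minus_faz"

    def test_annulus_area_matches_analytic(self):
        scale = 5.0
        grid = 500  # 2.5 mm field
        faz = np.zeros((grid, grid), bool)
        rr, cc = disk(((grid - 1) / 2, (grid - 1) / 2), 0.3 * 1000 / scale)
        faz[rr, cc] = True
        region = define_region(faz, scale, outer_radius_mm=1.0)
        analytic = np.pi * (1.0**2 - 0.3**2)
        assert region.area_mm2 == pytest.approx(analytic, rel=0.02)

    def test_outer_radius_inside_faz_rejected(self):
        faz = _disc_mask(52, pad=60)  # r = 0.3 mm at 5.859 um/px
        with pytest.raises(ValueError):
            define_region(faz, SCALE, outer_radius_mm=0.1)


class TestDensities:
    def test_perfusion_density_half_and_bounds(self):
        region = perfusion.RegionMask(np.ones((40, 40), bool), "annulus", SCALE)
        half = np.zeros((40, 40), bool)
        half[:20] = True
        assert perfusion_density(VesselMask(half, "whole", SCALE), region) == 50.0
        empty = VesselMask(np.zeros((40, 40), bool), "whole", SCALE)
        assert perfusion_density(empty, region) == 0.0
        full = VesselMask(np.ones((40, 40), bool), "whole", SCALE)
        assert perfusion_density(full, region) == 100.0

    def test_perfusion_density_equals_pixel_count_oracle(self, rng):
        mask = rng.random((40, 40)) < 0.4
        reg = rng.random((40, 40)) < 0.7
        region = perfusion.RegionMask(reg, "annulus", SCALE)
        got = perfusion_density(VesselMask(mask, "whole", SCALE), region)
        # brute-force double loop
        num = sum(mask[i, j] and reg[i, j] for i in range(40) for j in range(40))
        den = int(reg.sum())
        assert got == pytest.approx(100.0 * num / den)

    def test_vessel_density_unit_case(self):
        # 1 mm centerline in a 1 mm^2 region at 10 um/px
        scale = 10.0
        grid = 100
        sk = np.zeros((grid, grid), bool)
        sk[50, 0:101] = True  # 100 px row -> clipped to grid: 100 px, 99 steps
        sk[50, :] = True
        skel = SkeletonMap(sk, scale)
        region = perfusion.RegionMask(np.ones((grid, grid), bool), "annulus", scale)
        # length = 99 axial steps x 0.01 mm = 0.99 mm over exactly 1 mm^2
        assert vessel_density(skel, region) == pytest.approx(0.99)

    def test_vessel_density_matches_step_count_oracle(self, rng):
        scale = 8.0
        m = rng.random((60, 60)) < 0.25
        skel = skeletonize_mask(VesselMask(m, "whole", scale))
        reg = np.ones((60, 60), bool)
        region = perfusion.RegionMask(reg, "annulus", scale)
        # oracle: count unique neighbour pairs
        total = 0.0
        s = skel.skeleton
        for i in range(60):
            for j in range(60):
                if not s[i, j]:
                    continue
                for di, dj, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)),
                                  (1, -1, np.sqrt(2))):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < 60 and 0 <= jj < 60 and s[ii, jj]:
                        total += w * scale / 1000.0
        assert vessel_density(skel, region) == pytest.approx(total / region.area_mm2)

    def test_empty_skeleton_density_zero(self):
        region = perfusion.RegionMask(np.ones((30, 30), bool), "annulus", SCALE)
        assert vessel_density(SkeletonMap(np.zeros((30, 30), bool), SCALE), region) == 0.0


class TestLayerMetrics:
    def _components(self, truth, scale):
        whole = VesselMask(truth.vessel_mask_true, "whole", scale)
        lv = VesselMask(truth.lv_mask_true, "large_vessel", scale)
        cp = VesselMask(truth.vessel_mask_true & ~truth.lv_mask_true, "capillary", scale)
        sw = skeletonize_mask(whole)
        return whole, lv, cp, sw

    def test_additivity_and_oracle_on_ground_truth(self, default_slab):
        img, truth = default_slab
        scale = img.scale_um_per_px
        whole, lv, cp, sw = self._components(truth, scale)
        region = define_region(truth.faz_mask_true, scale)
        m = layer_metrics(whole, lv, cp, sw,
                          restrict_skeleton(sw, lv.mask),
                          restrict_skeleton(sw, cp.mask), region)
        assert m.pd_lv + m.pd_cp == pytest.approx(m.pd_whole, abs=1e-10)
        assert m.vd_lv + m.vd_cp == pytest.approx(m.vd_whole, abs=1e-10)
        # stage-level oracle equality
        assert m.pd_whole == perfusion_density(whole, region)
        assert m.vd_whole == vessel_density(sw, region)

    def test_empty_large_vessel_compartment(self):
        m = np.zeros((50, 50), bool)
        m[10:12, :] = True
        whole = VesselMask(m, "whole", SCALE)
        lv = VesselMask(np.zeros_like(m), "large_vessel", SCALE)
        cp = VesselMask(m, "capillary", SCALE)
        sw = skeletonize_mask(whole)
        region = perfusion.RegionMask(np.ones_like(m), "annulus", SCALE)
        out = layer_metrics(whole, lv, cp, sw,
                            restrict_skeleton(sw, lv.mask),
                            restrict_skeleton(sw, cp.mask), region)
        assert out.pd_lv == 0.0
        assert out.pd_cp == out.pd_whole

    def test_non_partition_rejected(self):
        m = np.ones((10, 10), bool)
        whole = VesselMask(m, "whole", SCALE)
        lv = VesselMask(m, "large_vessel", SCALE)  # overlaps cp below
        cp = VesselMask(m, "capillary", SCALE)
        sw = skeletonize_mask(whole)
        region = perfusion.RegionMask(np.ones_like(m), "annulus", SCALE)
        with pytest.raises(ValueError, match="partition"):
            layer_metrics(whole, lv, cp, sw, sw, sw, region)

    def test_pd_monotone_in_mask_pixels(self, rng):
        reg = np.ones((30, 30), bool)
        region = perfusion.RegionMask(reg, "annulus", SCALE)
        m = rng.random((30, 30)) < 0.2
        base = perfusion_density(VesselMask(m, "whole", SCALE), region)
        m2 = m.copy()
        m2[0, 0] = True
        m2[15, 15] = True
        assert perfusion_density(VesselMask(m2, "whole", SCALE), region) >= base
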