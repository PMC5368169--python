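"""Descriptor geometry against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from skimage import draw, measure

from florascreen import morphometrics as M
from florascreen.morphometrics import BinaryMask

from conftest import random_blob, raster_disc, raster_square


class TestAreaPerimeter:
    def test_disc_area_matches_closed_form(self, disc100):
        area, _ = M.measure_area_perimeter(disc100)
        assert area == pytest.approx(math.pi * 100**2, rel=0.01)

    def test_single_pixel_area_scales_with_resolution(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True
        area, _ = M.measure_area_perimeter(BinaryMask(grid, mm_per_px=0.5))
        assert area == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "mask,expected",
        [(raster_square(100), 400.0), (raster_disc(100), 200 * math.pi)],
        ids=["square", "disc"],
    )
    def test_perimeter_matches_closed_form(self, mask, expected):
        _, per = M.measure_area_perimeter(mask)
        assert per == pytest.approx(expected, rel=0.02)

    def test_empty_mask_raises_signal_with_identity(self):
        mask = BinaryMask(np.zeros((5, 5), bool), plant_id="p7", day=12)
        with pytest.raises(M.EmptyMaskError, match="p7"):
            M.measure_area_perimeter(mask)

    def test_area_equals_pixel_count_on_random_shapes(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            mask = random_blob(rng)
            area, _ = M.measure_area_perimeter(mask)
            assert area == float(mask.grid.sum())

    def test_perimeter_agrees_with_crofton_oracle_on_random_shapes(self):
        # two independent estimators of the same boundary length
        rng = np.random.default_rng(12)
        for _ in range(100):
            mask = random_blob(rng)
            _, per = M.measure_area_perimeter(mask, method="contour")
            crofton = measure.perimeter_crofton(mask.grid, directions=4)
            assert per == pytest.approx(crofton, rel=0.12)


class TestHull:
    def test_four_corner_pixels_use_outer_corner_convention(self):
        grid = np.zeros((14, 14), bool)
        for r, c in [(2, 2), (2, 11), (11, 2), (11, 11)]:
            grid[r, c] = True
        _, area, _ = M.compute_hull(BinaryMask(grid))
        assert area == pytest.approx(100.0)  # 10x10 outer-corner square

    def test_filled_square_hull_equals_own_area(self):
        mask = raster_square(50)
        _, hull_area, _ = M.compute_hull(mask)
        assert hull_area == pytest.approx(50.0**2)

    def test_plus_shape_hull_exceeds_area(self):
        grid = np.zeros((32, 32), bool)
        grid[12:20, 4:28] = True
        grid[4:28, 12:20] = True
        mask = BinaryMask(grid)
        area, _ = M.measure_area_perimeter(mask)
        _, hull_area, _ = M.compute_hull(mask)
        assert hull_area > area

    def test_hull_is_convex(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            poly, _, _ = M.compute_hull(random_blob(rng))
            v = np.diff(np.vstack([poly, poly[:2]]), axis=0)
            cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
            assert (cross >= -1e-9).all() or (cross <= 1e-9).all()


class TestSkeleton:
    def test_horizontal_bar_length(self):
        grid = np.zeros((5, 105), bool)
        grid[2, 2:103] = True
        # brute force: a 1-px line of n pixels has n-1 unit steps
        assert M.compute_skeleton_length(BinaryMask(grid)) == pytest.approx(
            100.0, abs=2.0)

    def test_right_angle_bars_sum_arm_lengths(self):
        grid = np.zeros((64, 64), bool)
        grid[30:33, 5:60] = True
        grid[5:60, 30:33] = True
        length = M.compute_skeleton_length(BinaryMask(grid))
        assert length == pytest.approx(55 + 55, rel=0.10)

    def test_disc_skeleton_far_shorter_than_perimeter(self, disc100):
        _, per = M.measure_area_perimeter(disc100)
        assert M.compute_skeleton_length(disc100) < per / 5


class TestDescriptorFormulas:
    def test_roundness_closed_forms(self):
        r = 3.7
        assert M.roundness(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)
        s = 2.5
        assert M.roundness(s**2, 4 * s) == pytest.approx(math.pi / 4)
        # 10:1 rectangle
        assert M.roundness(10.0, 22.0) == pytest.approx(
            4 * math.pi * 10 / 22**2)

    def test_roundness_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            M.roundness(0.0, 1.0)

    def test_roundness2_equilateral_triangle(self):
        s = 1.0
        area = math.sqrt(3) / 4 * s**2
        assert M.roundness2(area, 3 * s) == pytest.approx(
            math.pi * math.sqrt(3) / 9)

    def test_isotropy_regular_hexagon(self):
        ang = np.arange(6) * math.pi / 3
        hexagon = np.column_stack([np.cos(ang), np.sin(ang)])
        area = 3 * math.sqrt(3) / 2
        assert M.isotropy(hexagon) == pytest.approx(
            4 * math.pi * area / 36, rel=1e-6)
        assert M.isotropy(hexagon) == pytest.approx(0.9069, abs=1e-3)

    def test_eccentricity_closed_forms(self):
        # equal moments: circle
        assert M.eccentricity((4.0, 4.0, 0.0)) == 0.0
        # ellipse with a = 2b: mu20 ∝ a², mu02 ∝ b²
        assert M.eccentricity((4.0, 1.0, 0.0)) == pytest.approx(
            math.sqrt(3) / 2)
        assert M.eccentricity((0.0, 0.0, 0.0)) == 0.0

    def test_eccentricity_rotation_invariant_on_raster(self):
        grid = np.zeros((60, 100), bool)
        rr, cc = draw.ellipse(30, 50, 14, 40)
        grid[rr, cc] = True
        def ecc(g):
            return M.describe(BinaryMask(g)).eccentricity
        assert ecc(grid) == pytest.approx(ecc(grid.T))

    def test_rms_centered_square_closed_form(self, square100):
        # circular-segment closed form: r=1/sqrt(pi), d=1/2 per unit side
        r, d = 1 / math.sqrt(math.pi), 0.5
        seg = r**2 * math.acos(d / r) - d * math.sqrt(r**2 - d**2)
        inter = 1 - 4 * seg
        expected = 2 * (1 - inter) / inter  # = 0.19934
        desc = M.describe(square100)
        assert desc.rms == pytest.approx(expected, abs=0.01)

    def test_rms_translation_invariance(self):
        poly = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        v0 = M.rms(poly, (2.0, 2.0))
        v1 = M.rms(poly + 100.0, (102.0, 102.0))
        assert v0 == pytest.approx(v1, rel=1e-9)

    def test_compactness_plus_shape(self):
        # plus of 5 unit squares: hull is the octagon of area 7
        grid = np.zeros((32, 32), bool)
        grid[12:20, 4:28] = True
        grid[4:28, 12:20] = True
        mask = BinaryMask(grid)
        area, _ = M.measure_area_perimeter(mask)
        _, hull_area, _ = M.compute_hull(mask)
        assert M.compactness(area, hull_area) == pytest.approx(5 / 7, rel=0.01)

    def test_sol_bar_closed_form(self):
        grid = np.zeros((5, 105), bool)
        grid[2, 2:103] = True
        mask = BinaryMask(grid)
        area, _ = M.measure_area_perimeter(mask)
        L = M.compute_skeleton_length(mask)
        assert M.sol(L, area) == pytest.approx(100**2 / 101, rel=0.05)


class TestDescribe:
    def test_deterministic(self, disc100):
        assert M.describe(disc100).as_dict() == M.describe(disc100).as_dict()

    def test_mirror_symmetry_exact(self):
        rng = np.random.default_rng(3)
        mask = random_blob(rng)
        mirrored = BinaryMask(mask.grid[:, ::-1].copy())
        a, b = M.describe(mask).as_dict(), M.describe(mirrored).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-6), key

    def test_rotation_90_symmetry_exact(self):
        rng = np.random.default_rng(4)
        mask = random_blob(rng)
        rotated = BinaryMask(np.rot90(mask.grid).copy())
        a, b = M.describe(mask).as_dict(), M.describe(rotated).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-6), key

    def test_disc_fixture_closed_forms(self, disc100):
        d = M.describe(disc100)
        assert abs(d.roundness - 1) < 0.02
        assert d.eccentricity < 0.02
        assert d.rms < 0.02
        assert abs(d.compactness - 1) < 0.02

    def test_scale_covariance(self):
        rng = np.random.default_rng(6)
        grid = random_blob(rng).grid
        d1 = M.describe(BinaryMask(grid, mm_per_px=1.0))
        d2 = M.describe(BinaryMask(grid, mm_per_px=2.0))
        assert d2.area == pytest.approx(4 * d1.area, rel=0.01)
        assert d2.perimeter == pytest.approx(2 * d1.perimeter, rel=0.01)
        for name in ("roundness", "roundness2", "isotropy", "eccentricity",
                     "rms", "compactness", "sol"):
            assert getattr(d2, name) == pytest.approx(
                getattr(d1, name), rel=0.01), name

    def test_roundness2_bounds_roundness_on_blob_suite(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            d = M.describe(random_blob(rng, size=70))
            assert d.roundness2 >= d.roundness - 1e-12
            assert 0 < d.compactness <= 1

    def test_multi_component_mask_keeps_largest_and_flags(self):
        grid = np.zeros((60, 60), bool)
        rr, cc = draw.disk((20, 20), 12)
        grid[rr, cc] = True
        grid[50, 50] = True  # speck
        d = M.describe(BinaryMask(grid))
        assert any(f.startswith("multi-component") for f in d.qc_flags)
        assert d.area == pytest.approx(float(grid.sum()) - 1)

    def test_two_tip_mask_falls_back_to_hull(self):
        # slender 2-lobed bar: tip polygon degenerate, hull fallback flagged
        grid = np.zeros((20, 80), bool)
        grid[8:12, 4:76] = True
        d = M.describe(BinaryMask(grid))
        assert "tip-fallback" in d.qc_flags


class TestLeafTips:
    def test_star_tips_recovered(self):
        # 6-armed star: 6 tips at known angles
        size = 201
        grid = np.zeros((size, size), bool)
        c = size // 2
        for k in range(6):
            ang = k * math.pi / 3
            for t in np.linspace(0, 1, 400):
                r = 90 * t
                rr = int(round(c + r * math.sin(ang)))
                cc = int(round(c + r * math.cos(ang)))
                grid[max(rr - 4, 0):rr + 5, max(cc - 4, 0):cc + 5] = True
        tips = M.detect_leaf_tips(BinaryMask(grid))
        assert len(tips) == 6
        radii = np.hypot(tips[:, 0] - c - 0.5, tips[:, 1] - c - 0.5)
        assert (radii > 70).all()
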