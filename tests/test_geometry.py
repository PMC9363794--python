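"""Center extraction: connected components, minimum enclosing circle, centers."""

import math

import numpy as np
import pytest

from dfa_meter.geometry import (
    MissingClassError,
    extract_centers,
    largest_component,
    min_enclosing_circle,
)

from conftest import brute_force_mec, flood_fill_components


class TestLargestComponent:
    def test_picks_larger_blob(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1, 1:4] = 1  # 3-pixel blob
        mask[5:6, 5:10] = 1  # 5-pixel blob
        pts = largest_component(mask, 1)
        assert len(pts) == 5
        assert set(map(tuple, pts)) == {(x, 5) for x in range(5, 10)}

    def test_absent_class_gives_empty_set(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        assert largest_component(mask, 2).shape == (0, 2)

    def test_diagonal_pixels_are_connected(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = 1
        assert len(largest_component(mask, 1)) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((32, 32)) < 0.35).astype(np.uint8)
        result = set(map(tuple, largest_component(mask, 1)))
        comps = flood_fill_components(mask == 1)
        largest = max(comps, key=len)
        assert len(result) == len(largest)
        assert result == set(largest)


class TestMinEnclosingCircle:
    def test_single_point(self):
        fit = min_enclosing_circle([(5, 5)])
        assert (fit.cx, fit.cy, fit.radius) == (5.0, 5.0, 0.0)

    def test_diameter_pair(self):
        fit = min_enclosing_circle([(0, 0), (2, 0)])
        assert (fit.cx, fit.cy, fit.radius) == (1.0, 0.0, 1.0)

    def test_obtuse_triangle_uses_diameter(self):
        fit = min_enclosing_circle([(0, 0), (4, 0), (2, 2)])
        assert (fit.cx, fit.cy, fit.radius) == (2.0, 0.0, 2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            min_enclosing_circle([])

    def test_collinear_points(self):
        fit = min_enclosing_circle([(0, 0), (1, 1), (2, 2), (5, 5)])
        assert fit.radius == pytest.approx(math.hypot(2.5, 2.5), abs=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        pts = rng.uniform(-50, 50, size=(n, 2))
        fit = min_enclosing_circle(pts)
        oracle = brute_force_mec(pts)
        assert fit.radius == pytest.approx(oracle.radius, abs=1e-6)
        # containment and minimality
        for p in pts:
            assert math.hypot(p[0] - fit.cx, p[1] - fit.cy) <= fit.radius + 1e-7

    def test_matches_shapely_on_large_blob(self):
        shapely = pytest.importorskip("shapely")
        from shapely import MultiPoint, minimum_bounding_radius

        rng = np.random.default_rng(3)
        pts = rng.normal(0, 20, size=(500, 2)).round(1)
        fit = min_enclosing_circle(pts)
        ref_radius = minimum_bounding_radius(MultiPoint([tuple(p) for p in pts]))
        assert fit.radius == pytest.approx(ref_radius, rel=1e-6)


class TestExtractCenters:
    def _square_mask(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10:21, 10:21] = 1  # 11x11 square, center (15, 15)
        mask[30:33, 30:33] = 2
        return mask

    @pytest.mark.parametrize("method", ["circle", "rectangle"])
    def test_square_center_symmetry(self, method):
        centers = extract_centers(self._square_mask(), method=method)
        assert (centers.ox, centers.oy) == (15.0, 15.0)
        assert (centers.mx, centers.my) == (31.0, 31.0)

    def test_circle_and_rectangle_agree_on_disc(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[(xx - 20) ** 2 + (yy - 30) ** 2 <= 100] = 1
        mask[(xx - 50) ** 2 + (yy - 30) ** 2 <= 64] = 2
        c1 = extract_centers(mask, method="circle")
        c2 = extract_centers(mask, method="rectangle")
        assert abs(c1.ox - c2.ox) <= 1 and abs(c1.oy - c2.oy) <= 1
        assert abs(c1.mx - c2.mx) <= 1 and abs(c1.my - c2.my) <= 1

    def test_missing_class_error_names_class(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2, 2] = 1
        with pytest.raises(MissingClassError) as excinfo:
            extract_centers(mask)
        assert excinfo.value.class_code == 2

    def test_invariant_to_speckle_of_other_class(self):
        mask = self._square_mask()
        base = extract_centers(mask)
        noisy = mask.copy()
        noisy[0, 0] = 2  # smaller macula speckle, away from the main blob
        noisy[39, 0] = 1  # smaller disc speckle
        again = extract_centers(noisy)
        assert (base.ox, base.oy) == (again.ox, again.oy)
        assert (base.mx, base.my) == (again.mx, again.my)

    def test_synthetic_round_trip(self, desk_scenes, desk_masks):
        """Centers recovered from rendered labels match scene ground truth."""
        for scene, mask in zip(desk_scenes, desk_masks):
            centers = extract_centers(mask)
            assert math.hypot(
                centers.ox - scene.disc_center[0], centers.oy - scene.disc_center[1]
            ) <= 1.5
            assert math.hypot(
                centers.mx - scene.fovea_center[0], centers.my - scene.fovea_center[1]
            ) <= 1.5
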