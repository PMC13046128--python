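"""Polar mapping, laterality mirroring and distance normalisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordpolar import geometry as geo
from cordpolar.imgproc import SectionGeometry


def blob_mask(shape=(40, 40), seed=3):
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, bool)
    mask[10:30, 8:25] = rng.random((20, 17)) > 0.4
    mask[15, 15] = True
    return mask


class TestRoiCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 7] = True
        assert geo.roi_centroid(mask) == (7.0, 3.0)

    def test_centred_disk(self):
        yy, xx = np.mgrid[0:41, 0:41]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 64
        cx, cy = geo.roi_centroid(mask)
        assert cx == pytest.approx(20, abs=0.5)
        assert cy == pytest.approx(20, abs=0.5)

    def test_matches_explicit_pixel_loop(self):
        mask = blob_mask()
        sx = sy = n = 0
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                if mask[r, c]:
                    sx += c
                    sy += r
                    n += 1
        assert geo.roi_centroid(mask) == (sx / n, sy / n)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            geo.roi_centroid(np.zeros((5, 5), bool))


class TestPolarCoords:
    def test_cell_above_canal_is_dorsal_90(self):
        d, a = geo.polar_coords((50.0, 10.0), (50.0, 50.0), 1.0, True)
        assert a == pytest.approx(90.0)
        assert d == pytest.approx(40.0)

    def test_right_is_zero_ventral_is_270(self):
        _, a = geo.polar_coords((80.0, 50.0), (50.0, 50.0), 1.0, True)
        assert a == pytest.approx(0.0)
        _, a = geo.polar_coords((50.0, 90.0), (50.0, 50.0), 1.0, True)
        assert a == pytest.approx(270.0)

    def test_three_four_five(self):
        d, _ = geo.polar_coords((3.0, 4.0), (0.0, 0.0), 1.0, True)
        assert d == pytest.approx(5.0)

    def test_pixel_size_scales_distance(self):
        d, _ = geo.polar_coords((10.0, 0.0), (0.0, 0.0), 0.57, True)
        assert d == pytest.approx(5.7)

    def test_upside_down_mount_flips_dorsal(self):
        _, a = geo.polar_coords((50.0, 90.0), (50.0, 50.0), 1.0, False)
        assert a == pytest.approx(90.0)

    def test_coincident_centroids_raise(self):
        with pytest.raises(ValueError):
            geo.polar_coords((5.0, 5.0), (5.0, 5.0), 1.0)

    def test_translation_invariance(self, rng):
        cell = (12.3, 40.2)
        canal = (30.0, 25.0)
        d0, a0 = geo.polar_coords(cell, canal, 1.0)
        for _ in range(5):
            t = rng.normal(size=2) * 50
            d, a = geo.polar_coords((cell[0] + t[0], cell[1] + t[1]),
                                    (canal[0] + t[0], canal[1] + t[1]), 1.0)
            assert d == pytest.approx(d0)
            assert a == pytest.approx(a0)


class TestMirror:
    @pytest.mark.parametrize("theta, expected", [
        (135.0, 45.0),
        (225.0, 315.0),
        (45.0, 45.0),
        (315.0, 315.0),
        (90.0, 90.0),     # boundary angles stay put
        (270.0, 270.0),
        (180.0, 0.0),
    ])
    def test_values(self, theta, expected):
        assert geo.mirror_left_to_right(theta) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=360.0, exclude_max=True))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_mirror_properties(self, theta):
        m = geo.mirror_left_to_right(theta)
        # idempotent, preserves the dorsoventral component, lands right-side
        assert geo.mirror_left_to_right(m) == pytest.approx(m)
        assert abs(math.sin(math.radians(m))
                   - math.sin(math.radians(theta))) < 1e-9
        assert not (90.0 < m < 270.0)


class TestNormaliseDistance:
    def test_zero_at_canal_centroid(self, small_geometry):
        v = geo.normalise_distance(small_geometry.canal_centroid,
                                   small_geometry, "radial_fraction")
        assert v == 0.0

    def test_one_at_ray_boundary(self, small_geometry):
        cx, cy = small_geometry.canal_centroid
        boundary = geo.RadialBoundary(small_geometry.gray_mask, (cx, cy))
        for angle in (0.0, 45.0, 250.0, 300.0):
            r = float(boundary(angle))
            x = cx + r * math.cos(math.radians(angle))
            y = cy - r * math.sin(math.radians(angle))
            v = geo.normalise_distance((x, y), small_geometry,
                                       "radial_fraction")
            assert v == pytest.approx(1.0, abs=0.02)

    def test_monotone_along_ray(self, small_geometry):
        cx, cy = small_geometry.canal_centroid
        boundary = geo.RadialBoundary(small_geometry.gray_mask, (cx, cy))
        angle = 305.0
        rmax = float(boundary(angle))
        values = []
        for u in np.linspace(0.05, 0.98, 25):
            x = cx + u * rmax * math.cos(math.radians(angle))
            y = cy - u * rmax * math.sin(math.radians(angle))
            values.append(geo.normalise_distance((x, y), small_geometry,
                                                 "radial_fraction"))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_edge_map_is_one_at_deepest_pixel(self, small_geometry):
        depth = geo.edge_depth_map(small_geometry.gray_mask)
        r, c = np.unravel_index(np.argmax(depth), depth.shape)
        v = geo.normalise_distance((float(c), float(r)), small_geometry,
                                   "edge_map")
        assert v == pytest.approx(1.0, abs=1e-6)

    def test_outside_mask_raises(self, small_geometry):
        with pytest.raises(ValueError):
            geo.normalise_distance((1.0, 1.0), small_geometry)

    def test_unknown_variant_raises(self, small_geometry):
        with pytest.raises(ValueError):
            geo.normalise_distance(small_geometry.canal_centroid,
                                   small_geometry, "nope")

    def test_canal_over_depthmax_scales_with_canal_distance(self,
                                                            small_geometry):
        cx, cy = small_geometry.canal_centroid
        v1 = geo.normalise_distance((cx + 20, cy), small_geometry,
                                    "canal_over_depthmax")
        v2 = geo.normalise_distance((cx + 40, cy), small_geometry,
                                    "canal_over_depthmax")
        assert v2 == pytest.approx(2 * v1)
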