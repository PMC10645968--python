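"""Morphometric operations against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from spikegrain.morphometry import (boundary_polygon, feret_diameters,
                                    fit_ellipse_moments, measure_grain_mask,
                                    polygon_area, polygon_perimeter,
                                    shape_descriptors, smooth_polygon)
from spikegrain.simulate import _stamp_ellipse


def _disk(r, cx=65.3, cy=65.7, shape=(140, 140)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _aa_ellipse(a, b, angle, shape=(200, 200), cx=100.3, cy=100.6):
    canvas = np.zeros(shape)
    _stamp_ellipse(canvas, cx, cy, a, b, angle, 1.0, 0.0)
    return canvas > 0.5


class TestBoundaryPolygon:
    def test_single_pixel_diamond(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        poly = boundary_polygon(mask)
        assert polygon_perimeter(poly) == pytest.approx(2 * math.sqrt(2),
                                                        rel=1e-9)

    def test_square_polygon_area_convention(self):
        # 10x10 filled square: iso-0.5 contour passes midway between the
        # outermost inside pixel centres and the outside, area 10*10 minus
        # the four marching-squares corner cuts of 1/8 px^2 each
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        poly = boundary_polygon(mask)
        assert polygon_area(poly) == pytest.approx(100 - 0.5)

    def test_polygon_closed(self):
        poly = boundary_polygon(_disk(20))
        assert np.allclose(poly[0], poly[-1])

    def test_hull_contains_polygon(self):
        from scipy.spatial import ConvexHull
        poly = boundary_polygon(_aa_ellipse(40, 15, 30))
        hull = ConvexHull(poly[:-1])
        assert hull.volume >= polygon_area(poly) - 1e-9

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            boundary_polygon(np.zeros((5, 5), bool))


class TestFeret:
    def test_rectangle_closed_form(self):
        mask = np.zeros((40, 80), bool)
        mask[10:30, 10:70] = True  # 60 x 20 px
        feret, angle, minferet, deg = feret_diameters(boundary_polygon(mask))
        assert not deg
        assert feret == pytest.approx(math.hypot(60, 20), rel=0.02)
        assert minferet == pytest.approx(20.0, rel=0.01)

    def test_disk_both_calipers_near_diameter(self):
        feret, _, minferet, _ = feret_diameters(boundary_polygon(_disk(50)))
        assert feret == pytest.approx(100.0, rel=0.015)
        assert minferet == pytest.approx(100.0, rel=0.015)

    @pytest.mark.parametrize("angle", [0, 17, 45, 77, 133])
    def test_rotated_ellipse_rotation_invariance(self, angle):
        poly = boundary_polygon(_aa_ellipse(40, 15, angle))
        feret, _, minferet, _ = feret_diameters(poly)
        assert feret == pytest.approx(80.0, rel=0.02)
        assert minferet == pytest.approx(30.0, rel=0.02)

    def test_collinear_degenerate_flagged(self):
        poly = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0], [0.0, 0.0]])
        feret, _, minferet, deg = feret_diameters(poly)
        assert deg
        assert feret == pytest.approx(10.0)
        assert minferet == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_brute_force_caliper_oracle(self, seed):
        """Rotating calipers vs exhaustive pairwise / 0.1-degree rotation."""
        rng = np.random.default_rng(seed)
        canvas = np.zeros((90, 90))
        _stamp_ellipse(canvas, 45 + rng.uniform(), 45 + rng.uniform(),
                       rng.uniform(15, 30), rng.uniform(6, 14),
                       rng.uniform(0, 180), 1.0, 0.0)
        mask = canvas > 0.5
        assert mask.sum() <= 5000
        poly = boundary_polygon(mask)
        feret, _, minferet, _ = feret_diameters(poly)
        pts = poly[:-1]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert feret == pytest.approx(d.max(), rel=1e-9)
        # exhaustive min directional width on the same smoothed outline
        sm = smooth_polygon(poly)[:-1]
        thetas = np.deg2rad(np.arange(0, 180, 0.1))
        dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        proj = sm @ dirs.T
        widths = proj.max(axis=0) - proj.min(axis=0)
        assert minferet == pytest.approx(widths.min(), rel=0.005)


class TestEllipseFit:
    def test_axis_aligned_ellipse_axes(self):
        coords = np.argwhere(_aa_ellipse(40, 15, 0))
        major, minor, angle, deg = fit_ellipse_moments(coords)
        assert not deg
        assert major == pytest.approx(80, rel=0.02)
        assert minor == pytest.approx(30, rel=0.02)
        assert angle == pytest.approx(90, abs=1.5)  # long axis vertical

    def test_disk_symmetric(self):
        coords = np.argwhere(_disk(40))
        major, minor, _, _ = fit_ellipse_moments(coords)
        assert major / minor == pytest.approx(1.0, rel=0.01)

    def test_rotation_equivariance(self):
        c0 = np.argwhere(_aa_ellipse(40, 15, 25))
        c90 = np.argwhere(_aa_ellipse(40, 15, 115))
        maj0, min0, ang0, _ = fit_ellipse_moments(c0)
        maj90, min90, ang90, _ = fit_ellipse_moments(c90)
        assert maj90 == pytest.approx(maj0, rel=0.01)
        assert min90 == pytest.approx(min0, rel=0.01)
        assert (ang90 - ang0) % 180 == pytest.approx(90, abs=1.5)

    def test_equal_area_convention(self):
        coords = np.argwhere(_aa_ellipse(35, 20, 40))
        major, minor, _, _ = fit_ellipse_moments(coords)
        assert math.pi * major * minor / 4 == pytest.approx(len(coords),
                                                            rel=1e-6)

    def test_degenerate_line_flagged(self):
        coords = np.array([[5, c] for c in range(10)])
        major, minor, angle, deg = fit_ellipse_moments(coords)
        assert deg
        assert major == pytest.approx(10.0)


class TestShapeDescriptors:
    def test_perfect_circle_analytic(self):
        r = 3.0
        area, perim = math.pi * r**2, 2 * math.pi * r
        circ, ar, roundness, solidity = shape_descriptors(
            area, perim, 2 * r, 2 * r, area)
        assert circ == 1.0
        assert ar == 1.0
        assert roundness == pytest.approx(1.0)
        assert solidity == 1.0

    def test_elongation_drives_circularity_down(self):
        circs = []
        for L in (10, 40, 160):
            w = 2.0
            area, perim = L * w, 2 * (L + w)
            circ, *_ = shape_descriptors(area, perim, L, w, area)
            circs.append(circ)
        assert circs == sorted(circs, reverse=True)

    def test_two_to_one_ellipse_closed_form(self):
        a, b = 4.0, 2.0  # mm
        area = math.pi * a * b
        h = ((a - b) / (a + b)) ** 2
        perim = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        circ, ar, roundness, _ = shape_descriptors(area, perim, 2 * a, 2 * b,
                                                   area)
        assert circ == pytest.approx(0.8416, abs=0.001)
        assert roundness == pytest.approx(0.5, abs=1e-12)
        assert ar == pytest.approx(2.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            shape_descriptors(0.0, 1.0, 1.0, 1.0, 1.0)


class TestMeasureGrain:
    def test_scale_equivariance(self, cal10):
        from spikegrain.segment import set_scale
        m10 = measure_grain_mask(_aa_ellipse(35, 17, 20), cal10)
        cal20 = set_scale(200, 10)
        m20 = measure_grain_mask(_aa_ellipse(70, 34, 20, shape=(400, 400),
                                             cx=200.3, cy=200.6), cal20)
        assert m20.area_mm2 == pytest.approx(m10.area_mm2, rel=0.02)
        assert m20.feret_mm == pytest.approx(m10.feret_mm, rel=0.02)
        assert m20.minferet_mm == pytest.approx(m10.minferet_mm, rel=0.02)

    def test_feret_brackets_ellipse_axes(self, cal10):
        # convex shapes: feret >= major*(1-eps), minferet <= minor*(1+eps)
        m = measure_grain_mask(_aa_ellipse(40, 15, 63), cal10)
        eps = 0.03
        assert m.feret_mm >= m.major_mm * (1 - eps)
        assert m.minferet_mm <= m.minor_mm * (1 + eps)

    def test_representational_range(self, cal10):
        # areas spanning the 3-30.2 mm^2 field range survive unclipped
        small = measure_grain_mask(_disk(math.sqrt(3.04 / math.pi) * 10), cal10)
        large = measure_grain_mask(_disk(math.sqrt(30.15 / math.pi) * 10),
                                   cal10)
        assert small.area_mm2 == pytest.approx(3.04, rel=0.02)
        assert large.area_mm2 == pytest.approx(30.15, rel=0.02)

    def test_empty_mask_raises(self, cal10):
        with pytest.raises(ValueError):
            measure_grain_mask(np.zeros((5, 5), bool), cal10)


def test_measure_spike_matches_truth(rendered_spike, cal10):
    from spikegrain.morphometry import measure_spike
    from spikegrain.segment import label_particles, order_grains, \
        threshold_binarize

    _, img, truth, _ = rendered_spike
    labeled = label_particles(threshold_binarize(img), cal10)
    layout = order_grains(labeled)
    morphs = measure_spike(labeled, layout, cal10)
    assert len(morphs) == len(truth)
    # fixture image carries noise_sd=0.02, which roughens grain boundaries:
    # allow 2.5% on the width/area of individual noisy grains
    for m, g in zip(morphs, truth):
        assert m.feret_mm == pytest.approx(g.true_length_mm, rel=0.02)
        assert m.minferet_mm == pytest.approx(g.true_width_mm, rel=0.025)
        assert m.area_mm2 == pytest.approx(g.true_area_mm2, rel=0.025)
        assert m.centroid_mm[0] * 10 == pytest.approx(g.centroid_x_px, abs=2)
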