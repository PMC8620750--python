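"""Contour families against closed-form and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from seedshape.geometry import (
    BiSemiEllipseParams,
    ClosedContour,
    CompositionError,
    OpuntiaCurveParams,
    ParameterError,
    SpiralArcParams,
    SuperellipseParams,
    bi_semi_ellipse_lower,
    close_arc,
    contour_area,
    contour_perimeter,
    normalize_contour_pose,
    opuntia_radius,
    polygon_moments,
    principal_axes,
    resample_contour,
    sample_bi_semi_ellipse,
    sample_opuntia_curve,
    sample_spiral_arc,
    sample_superellipse,
    superellipse_area,
)
from seedshape.presets import get_model, list_models

REBUTIA_PARAMS = [
    SuperellipseParams(p=2.3, a=1.5, b=2.0),
    SuperellipseParams(p=2.6, a=1.0, b=2.1),
    SuperellipseParams(p=2.2, a=1.5, b=3.0),
]


class TestSuperellipse:
    def test_p2_is_unit_circle(self):
        c = sample_superellipse(SuperellipseParams(2, 1, 1), 1000)
        assert abs(c.area() - np.pi) / np.pi < 1e-4
        r = np.hypot(*c.vertices.T)
        assert np.max(np.abs(r - 1)) < 1e-12

    @given(
        p=st.floats(0.5, 8.0),
        a=st.floats(0.2, 4.0),
        b=st.floats(0.2, 4.0),
    )
    def test_vertices_satisfy_equation_and_symmetry(self, p, a, b):
        c = sample_superellipse(SuperellipseParams(p, a, b), 256)
        x, y = c.vertices.T
        res = np.abs(np.abs(x / a) ** p + np.abs(y / b) ** p - 1.0)
        assert res.max() < 1e-12
        # x -> -x and y -> -y map the vertex set onto itself
        from scipy.spatial import cKDTree

        tree = cKDTree(c.vertices)
        # fractional powers amplify machine eps near the axes (~eps^(2/p)),
        # so symmetry holds to well below vertex spacing, not to 1e-12
        tol = min(1e-3 * max(a, b), 0.1 * c.perimeter() / c.n)
        for flip in ([-1, 1], [1, -1]):
            d, _ = tree.query(c.vertices * flip)
            assert d.max() < tol

    @pytest.mark.parametrize("params", REBUTIA_PARAMS, ids=lambda p: f"p{p.p}")
    def test_area_matches_gamma_closed_form(self, params):
        c = sample_superellipse(params, 4000)
        exact = superellipse_area(params)
        assert abs(c.area() - exact) / exact < 1e-3

    def test_area_converges_monotonically(self):
        params = SuperellipseParams(2.6, 1.0, 2.1)
        exact = superellipse_area(params)
        errs = [abs(sample_superellipse(params, n).area() - exact) for n in (250, 500, 1000, 2000)]
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SuperellipseParams(-1, 1, 1)
        with pytest.raises(ParameterError):
            sample_superellipse(SuperellipseParams(2, 1, 1), 8)


class TestBiSemiEllipse:
    def test_no_flattening_equal_axes_is_circle(self):
        c = sample_bi_semi_ellipse(BiSemiEllipseParams(1, 1, 1, 0.0), 2000)
        r = np.hypot(*c.vertices.T)
        assert np.max(np.abs(r - 1)) < 1e-9

    def test_height_matches_blend_at_x0(self):
        # depth of the lower lobe at x=0 is b_lo*(1-f)*1 + f*b_lo*(1-f) = b_lo*(1-f^2)
        p = BiSemiEllipseParams(a=1, b_up=0.9, b_lo=0.5, flat_depth=0.6)
        c = sample_bi_semi_ellipse(p, 4000)
        height = c.vertices[:, 1].max() - c.vertices[:, 1].min()
        expected = 0.9 + 0.5 * (1 - 0.6**2)
        assert abs(height - expected) < 1e-4
        assert abs(bi_semi_ellipse_lower(p, 0.0) + 0.5 * (1 - 0.36)) < 1e-12

    def test_full_flattening_limit_removes_lower_area(self):
        lower_areas = []
        for f in (0.9, 0.99, 0.999):
            c = sample_bi_semi_ellipse(BiSemiEllipseParams(1, 1, 1, f), 2000)
            v = c.vertices
            lower_areas.append(abs(v[v[:, 1] < 0, 1]).max() if (v[:, 1] < 0).any() else 0.0)
        assert lower_areas[0] > lower_areas[1] > lower_areas[2]
        assert lower_areas[2] < 5e-3

    def test_symmetric_under_x_reflection(self):
        c = sample_bi_semi_ellipse(BiSemiEllipseParams(1.2, 0.8, 0.6, 0.4), 1000)
        _, ctr, _ = polygon_moments(c.vertices)
        assert abs(ctr[0]) < 1e-12


class TestSpiralArcs:
    def test_unit_radius_at_t1(self):
        arc = sample_spiral_arc(SpiralArcParams(1.0, 5.0), 100)
        assert np.allclose(arc.vertices[0], [np.cos(1), np.sin(1)])
        assert abs(np.hypot(*arc.vertices[-1]) - 5 ** (-1 / 3)) < 1e-12

    def test_radii_strictly_decreasing_for_negative_alpha(self):
        arc = sample_spiral_arc(SpiralArcParams(0.3, 5.0), 500)
        r = np.hypot(*arc.vertices.T)
        assert np.all(np.diff(r) < 0)

    def test_nested_intervals_share_vertices(self):
        outer = sample_spiral_arc(SpiralArcParams(0.3, 5.0, -1 / 3), 48)
        # t grid of [0.3, 5] at n=48 steps of 0.1 contains the [1, 5] t values
        inner_t = np.linspace(1.0, 5.0, 41)
        inner = np.column_stack([
            inner_t ** (-1 / 3) * np.cos(inner_t),
            inner_t ** (-1 / 3) * np.sin(inner_t),
        ])
        outer_set = set(map(tuple, np.round(outer.vertices, 9)))
        assert set(map(tuple, np.round(inner, 9))) <= outer_set

    def test_t_min_zero_rejected(self):
        with pytest.raises(ParameterError):
            SpiralArcParams(0.0, 5.0)

    def test_opuntia_radius_values(self):
        assert abs(opuntia_radius(2.0) - (0.5 + 1 - np.cos(2))) < 1e-15
        assert abs(opuntia_radius(2 * np.pi) - 1 / (2 * np.pi)) < 1e-15

    def test_opuntia_default_interval(self):
        arc = sample_opuntia_curve(OpuntiaCurveParams(), 200)
        assert arc.n == 200
        assert np.allclose(
            np.hypot(*arc.vertices[0]), opuntia_radius(2.0)
        )


class TestClosure:
    def test_chord_closure_of_half_circle_is_half_disc(self):
        t = np.linspace(0, np.pi, 2000)
        from seedshape.geometry import OpenArc

        arc = OpenArc(np.column_stack([np.cos(t), np.sin(t)]))
        c = close_arc(arc, method="chord")
        assert abs(c.area() - np.pi / 2) / (np.pi / 2) < 1e-3

    def test_chord_closure_area_matches_polar_sector_integral(self):
        arc = sample_spiral_arc(SpiralArcParams(1.0, 5.0), 4000)
        c = close_arc(arc, method="chord")
        sector, _ = quad(lambda t: 0.5 * t ** (-2 / 3), 1.0, 5.0)
        p1, p5 = arc.vertices[0], arc.vertices[-1]
        triangle = 0.5 * (p5[0] * p1[1] - p1[0] * p5[1])
        assert abs(c.area() - (sector + triangle)) / c.area() < 1e-3

    def test_silhouette_fragment_closure(self):
        # fragment = a circle through the arc's endpoints region
        arc = sample_spiral_arc(SpiralArcParams(0.3, 5.0), 500)
        ring = sample_superellipse(SuperellipseParams(2, 1.0, 1.0), 720)
        c = close_arc(arc, method="silhouette_fragment", fragment=ring)
        assert c.is_simple()
        assert c.area() > close_arc(arc, method="chord").area() * 0.5

    def test_self_intersecting_closure_raises(self):
        # nearly two full spiral turns: the chord must cross the arc
        arc = sample_spiral_arc(SpiralArcParams(0.1, 12.0), 1000)
        with pytest.raises(CompositionError):
            close_arc(arc, method="chord")


class TestMeasuresAndPresets:
    def test_unit_square_and_hexagon(self):
        sq = ClosedContour([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert contour_area(sq) == 1.0
        assert contour_perimeter(sq) == 4.0
        t = np.arange(6) * np.pi / 3
        hexagon = ClosedContour(np.column_stack([np.cos(t), np.sin(t)]))
        assert abs(contour_area(hexagon) - 3 * np.sqrt(3) / 2) < 1e-12

    def test_circle_perimeter(self):
        c = sample_superellipse(SuperellipseParams(2, 1, 1), 10000)
        assert abs(c.perimeter() - 2 * np.pi) / (2 * np.pi) < 1e-4

    def test_spiral_arc_length_matches_quadrature(self):
        arc = sample_spiral_arc(SpiralArcParams(1.0, 5.0, -1 / 3), 4000)
        integrand = lambda t: np.sqrt(t ** (-2 / 3) + (t ** (-4 / 3) / 3) ** 2)
        exact, _ = quad(integrand, 1.0, 5.0)
        assert abs(arc.length() - exact) / exact < 1e-3

    @pytest.mark.parametrize("name", list_models())
    def test_presets_are_simple_ccw_polygons(self, name):
        c = get_model(name)
        assert c.is_simple()
        assert c.area() > 0

    def test_doubling_n_refines_area(self):
        areas = {n: get_model("OPUNTIA1", n=n).area() for n in (500, 1000, 2000, 4000)}
        d1 = abs(areas[1000] - areas[500])
        d2 = abs(areas[2000] - areas[1000])
        d3 = abs(areas[4000] - areas[2000])
        assert d3 <= d2 <= d1

    def test_pose_normalization_orients_major_axis_vertically(self):
        c = get_model("HYLO1").rotated(0.9).translated(3.0, -2.0)
        n = normalize_contour_pose(c)
        L, W, theta = principal_axes(n)
        assert abs(abs(theta) - np.pi / 2) < 1e-6
        assert np.allclose(polygon_moments(n.vertices)[1], 0, atol=1e-9)

    def test_resample_preserves_area(self):
        c = get_model("PACHY1", n=2000)
        r = resample_contour(c, 400)
        assert abs(r.area() - c.area()) / c.area() < 2e-3
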