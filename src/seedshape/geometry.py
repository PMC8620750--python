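"""Closed-contour models of seed outlines.

Cactus seed profiles fall into a small number of geometric families:

* **Superellipses** ``|x/a|^p + |y/b|^p = 1`` (p > 2 gives the squarish
  outlines of *Rebutia* seeds; p = 2 is an ordinary ellipse).
* **Paired semi-ellipses** — an upper and a lower semi-ellipse with
  independent vertical semi-axes, the lower one flattened toward a chord to
  reproduce the straight hilum-side section of *Echinopsis*-type seeds.
* **Generalized Archimedean spiral arcs** ``r = t**alpha`` (alpha = -1/3) on a
  polar-angle interval; closed with a chord or an average-silhouette fragment
  they model the asymmetric seeds of *Hylocereus*, *Pachycereus*,
  *Ferocactus*, *Echinocactus* and *Pereskia*.
* The ***Opuntia* curve** ``r = 1/t + 1 - cos t``, a cardioid with a
  hyperbolic-spiral term added, for *Opuntia ficus-indica* seeds.

All curves are discretized as ordered vertex loops (``ClosedContour``) or open
polylines (``OpenArc``) in model units, counter-clockwise, y-axis up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, LineString

__all__ = [
    "SuperellipseParams",
    "BiSemiEllipseParams",
    "SpiralArcParams",
    "OpuntiaCurveParams",
    "ClosedContour",
    "OpenArc",
    "sample_superellipse",
    "sample_bi_semi_ellipse",
    "sample_spiral_arc",
    "sample_opuntia_curve",
    "close_arc",
    "contour_area",
    "contour_perimeter",
    "polygon_moments",
    "polygon_third_moment_y",
    "principal_axes",
    "normalize_contour_pose",
    "superellipse_area",
    "resample_contour",
]

DEFAULT_N = 2000


class ParameterError(ValueError):
    """Invalid curve parameters or vertex counts."""


class CompositionError(ValueError):
    """Arc closure produced a self-intersecting contour."""


# --------------------------------------------------------------------------
# parameter families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperellipseParams:
    """Exponent and semi-axes of ``|x/a|^p + |y/b|^p = 1``, p > 0."""

    p: float
    a: float
    b: float

    def __post_init__(self):
        if not (self.p > 0 and self.a > 0 and self.b > 0):
            raise ParameterError(f"superellipse requires p, a, b > 0, got {self}")


@dataclass(frozen=True)
class BiSemiEllipseParams:
    """Two semi-ellipses sharing the x-semi-axis ``a``.

    The upper lobe has vertical semi-axis ``b_up``; the lower (hilum-side)
    lobe of semi-axis ``b_lo`` is blended linearly toward the chord
    ``y = -b_lo*(1 - flat_depth)`` with blend weight ``flat_depth``, which
    flattens the hilum cup without breaking left-right symmetry.
    """

    a: float
    b_up: float
    b_lo: float
    flat_depth: float = 0.0

    def __post_init__(self):
        if not (self.a > 0 and self.b_up > 0 and self.b_lo > 0):
            raise ParameterError(f"semi-axes must be positive, got {self}")
        if not (0.0 <= self.flat_depth < 1.0):
            raise ParameterError(f"flat_depth must be in [0, 1), got {self.flat_depth}")


@dataclass(frozen=True)
class SpiralArcParams:
    """Polar arc ``r = t**alpha`` on ``t in [t_min, t_max]`` (radians)."""

    t_min: float
    t_max: float
    alpha: float = -1.0 / 3.0

    def __post_init__(self):
        if not (0 < self.t_min < self.t_max):
            raise ParameterError(
                f"need 0 < t_min < t_max (r diverges at t=0 for alpha<0), got {self}"
            )


@dataclass(frozen=True)
class OpuntiaCurveParams:
    """Polar arc ``r = 1/t + 1 - cos t``: cardioid plus hyperbolic spiral."""

    t_min: float = 2.0
    t_max: float = 6.0

    def __post_init__(self):
        if not (0 < self.t_min < self.t_max):
            raise ParameterError(f"need 0 < t_min < t_max, got {self}")


# --------------------------------------------------------------------------
# discrete curves
# --------------------------------------------------------------------------

@dataclass
class ClosedContour:
    """Ordered, implicitly closed, counter-clockwise vertex loop.

    ``units`` is one of ``"model"``, ``"mm"``, ``"px"`` and is carried for
    bookkeeping only; no conversion happens here.
    """

    vertices: np.ndarray
    units: str = "model"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ParameterError("a closed contour needs >= 3 (x, y) vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    @property
    def n(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        return _signed_area(self.vertices)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        _, c, _ = polygon_moments(self.vertices)
        return c

    def is_simple(self) -> bool:
        return LinearRing(self.vertices).is_simple

    def translated(self, dx: float, dy: float) -> "ClosedContour":
        return ClosedContour(self.vertices + [dx, dy], self.units)

    def scaled(self, sx: float, sy: float | None = None) -> "ClosedContour":
        sy = sx if sy is None else sy
        return ClosedContour(self.vertices * [sx, sy], self.units)

    def rotated(self, theta: float) -> "ClosedContour":
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        return ClosedContour(self.vertices @ rot.T, self.units)


@dataclass
class OpenArc:
    """Open polyline (e.g. a spiral arc before composition)."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ParameterError("an open arc needs >= 2 (x, y) vertices")
        self.vertices = v

    @property
    def n(self) -> int:
        return len(self.vertices)

    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * y2 - x2 * y))


def polygon_moments(v: np.ndarray):
    """Exact area, centroid and central second moments of a simple polygon.

    Returns ``(area, centroid, (mu20, mu02, mu11))`` with moments about the
    centroid: ``mu20 = ∫(x-cx)² dA`` etc.  Green's-theorem closed forms, so
    exact for polygonal input; area is positive for CCW loops.
    """
    x, y = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y2 - x2 * y
    a = 0.5 * cr.sum()
    if a == 0:
        raise ParameterError("degenerate polygon (zero area)")
    cx = np.sum((x + x2) * cr) / (6 * a)
    cy = np.sum((y + y2) * cr) / (6 * a)
    # second moments about the origin
    iyy = np.sum((x * x + x * x2 + x2 * x2) * cr) / 12.0  # ∫x² dA
    ixx = np.sum((y * y + y * y2 + y2 * y2) * cr) / 12.0  # ∫y² dA
    ixy = np.sum((x * y2 + 2 * x * y + 2 * x2 * y2 + x2 * y) * cr) / 24.0
    mu20 = iyy - a * cx * cx
    mu02 = ixx - a * cy * cy
    mu11 = ixy - a * cx * cy
    return float(a), np.array([cx, cy]), (float(mu20), float(mu02), float(mu11))


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _check_n(n: int, minimum: int) -> None:
    if n < minimum:
        raise ParameterError(f"vertex count {n} < minimum {minimum}")


def sample_superellipse(params: SuperellipseParams, n: int = DEFAULT_N) -> ClosedContour:
    """Sample ``|x/a|^p + |y/b|^p = 1`` at ``n`` vertices.

    Uses the closed-form parametrization ``x = a sgn(cos t)|cos t|^(2/p)``,
    ``y = b sgn(sin t)|sin t|^(2/p)`` with t uniform on [0, 2pi), which covers
    the corners of squarish (p > 2) outlines evenly.
    """
    _check_n(n, 16)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    e = 2.0 / params.p
    ct, st = np.cos(t), np.sin(t)
    x = params.a * np.sign(ct) * np.abs(ct) ** e
    y = params.b * np.sign(st) * np.abs(st) ** e
    return ClosedContour(np.column_stack([x, y]))


def superellipse_area(params: SuperellipseParams) -> float:
    """Closed-form area ``4ab * Gamma(1+1/p)^2 / Gamma(1+2/p)``."""
    from scipy.special import gamma

    p, a, b = params.p, params.a, params.b
    return 4.0 * a * b * gamma(1 + 1 / p) ** 2 / gamma(1 + 2 / p)


def bi_semi_ellipse_lower(params: BiSemiEllipseParams, x) -> np.ndarray:
    """Lower boundary of the paired-semi-ellipse model at abscissa ``x``.

    The pure lower semi-ellipse ``-b_lo*sqrt(1-(x/a)²)`` is blended with
    weight ``flat_depth`` toward the chord ``y = -b_lo*(1-flat_depth)``; at
    x = 0 the depth is ``b_lo*(1-flat_depth²)``.
    """
    x = np.asarray(x, dtype=float)
    f = params.flat_depth
    ell = -params.b_lo * np.sqrt(np.clip(1.0 - (x / params.a) ** 2, 0.0, None))
    chord = -params.b_lo * (1.0 - f)
    return (1.0 - f) * ell + f * chord


def sample_bi_semi_ellipse(params: BiSemiEllipseParams, n: int = DEFAULT_N) -> ClosedContour:
    """Sample the paired-semi-ellipse model at ``n`` vertices, CCW."""
    _check_n(n, 16)
    n_up = n // 2 + 1
    n_lo = n - n_up + 2
    # upper lobe from (a, 0) to (-a, 0), CCW
    u = np.linspace(0.0, np.pi, n_up)
    xu = params.a * np.cos(u)
    yu = params.b_up * np.sin(u)
    # lower chain from (-a, .) back toward (a, .)
    w = np.linspace(np.pi, 2.0 * np.pi, n_lo)[1:-1]
    xl = params.a * np.cos(w)
    yl = bi_semi_ellipse_lower(params, xl)
    v = np.column_stack([np.r_[xu, xl], np.r_[yu, yl]])
    return ClosedContour(v)


def _polar_arc(r: np.ndarray, t: np.ndarray) -> OpenArc:
    return OpenArc(np.column_stack([r * np.cos(t), r * np.sin(t)]))


def sample_spiral_arc(params: SpiralArcParams, n: int = DEFAULT_N) -> OpenArc:
    """Sample ``r = t**alpha`` at ``n`` evenly spaced polar angles."""
    _check_n(n, 2)
    t = np.linspace(params.t_min, params.t_max, n)
    return _polar_arc(t ** params.alpha, t)


def opuntia_radius(t) -> np.ndarray:
    """``r(t) = 1/t + 1 - cos t`` — hyperbolic spiral plus cardioid."""
    t = np.asarray(t, dtype=float)
    return 1.0 / t + 1.0 - np.cos(t)


def sample_opuntia_curve(params: OpuntiaCurveParams, n: int = DEFAULT_N) -> OpenArc:
    """Sample the Opuntia seed curve at ``n`` evenly spaced polar angles."""
    _check_n(n, 2)
    t = np.linspace(params.t_min, params.t_max, n)
    return _polar_arc(opuntia_radius(t), t)


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------

def close_arc(
    arc: OpenArc,
    method: str = "chord",
    fragment: ClosedContour | None = None,
) -> ClosedContour:
    """Close an open arc into a simple polygon.

    ``method="chord"`` joins the arc endpoints with a straight segment.
    ``method="silhouette_fragment"`` splices in the piece of ``fragment``
    (typically an average-silhouette contour registered to the arc's frame)
    running between the fragment vertices nearest to the two arc endpoints,
    choosing the traversal direction that does not cross the arc.
    """
    if arc.n < 3:
        raise ParameterError("need >= 3 arc vertices to close")
    if method == "chord":
        out = ClosedContour(arc.vertices)
    elif method == "silhouette_fragment":
        if fragment is None:
            raise ParameterError("silhouette_fragment closure needs a fragment contour")
        out = _splice_fragment(arc, fragment)
    else:
        raise ParameterError(f"unknown closure method {method!r}")
    if not out.is_simple():
        raise CompositionError(_describe_intersection(out))
    return out


def _splice_fragment(arc: OpenArc, fragment: ClosedContour) -> ClosedContour:
    frag = fragment.vertices
    a0, a1 = arc.vertices[0], arc.vertices[-1]
    i0 = int(np.argmin(np.hypot(*(frag - a0).T)))
    i1 = int(np.argmin(np.hypot(*(frag - a1).T)))
    m = len(frag)
    # two candidate paths around the fragment loop, from i1 back to i0
    fwd = frag[np.arange(i1, i1 + (i0 - i1) % m + 1) % m]
    bwd = frag[np.arange(i1, i1 - (i1 - i0) % m - 1, -1) % m]
    arc_line = LineString(arc.vertices)
    for path in sorted((fwd, bwd), key=len):
        if len(path) < 2:
            continue
        # drop splice endpoints: they duplicate the arc ends
        v = np.vstack([arc.vertices, path[1:-1]]) if len(path) > 2 else arc.vertices
        cand = ClosedContour(v)
        if cand.is_simple() and not LineString(path).crosses(arc_line):
            return cand
    raise CompositionError("no fragment splice avoids intersecting the arc")


def _describe_intersection(c: ClosedContour) -> str:
    v = np.vstack([c.vertices, c.vertices[:1]])
    segs = [LineString(v[i:i + 2]) for i in range(len(v) - 1)]
    for i in range(len(segs)):
        for j in range(i + 2, len(segs) - (1 if i == 0 else 0)):
            if segs[i].crosses(segs[j]):
                return f"closure self-intersects: segments {i} and {j} cross"
    return "closure self-intersects"


# --------------------------------------------------------------------------
# measures / utilities
# --------------------------------------------------------------------------

def contour_area(c: ClosedContour) -> float:
    """Shoelace area; positive for the CCW loops this module produces."""
    return c.area()


def contour_perimeter(c: ClosedContour) -> float:
    """Sum of segment lengths, closing edge included."""
    return c.perimeter()


def polygon_third_moment_y(v: np.ndarray) -> float:
    """Central third moment ``∫(y - cy)³ dA`` of a simple polygon (exact)."""
    _, c, _ = polygon_moments(v)
    y = v[:, 1] - c[1]
    x = v[:, 0] - c[0]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y2 - x2 * y
    return float(np.sum((y**3 + y**2 * y2 + y * y2**2 + y2**3) * cr) / 20.0)


def principal_axes(c: ClosedContour):
    """Moment-equivalent-ellipse axes ``(L, W, theta)`` of a contour.

    ``L``/``W`` are the full major/minor axes of the ellipse with the same
    area and central second moments; ``theta`` is the major-axis angle from
    the x-axis, in (-pi/2, pi/2].
    """
    a, _, (mu20, mu02, mu11) = polygon_moments(c.vertices)
    cov = np.array([[mu20, mu11], [mu11, mu02]]) / a
    lam, vec = np.linalg.eigh(cov)  # ascending
    L = 4.0 * np.sqrt(max(lam[1], 0.0))
    W = 4.0 * np.sqrt(max(lam[0], 0.0))
    vx, vy = vec[:, 1]
    theta = np.arctan2(vy, vx)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return float(L), float(W), float(theta)


def normalize_contour_pose(c: ClosedContour) -> ClosedContour:
    """Center a contour and put its major axis vertical, hilum end down.

    Centroid to the origin, principal axis along y; the vertical flip is
    chosen so the third central moment of y is non-negative (skew tail
    toward +y), the same blunt-hilum-end-down convention used for raster
    masks.
    """
    _, ctr, _ = polygon_moments(c.vertices)
    out = ClosedContour(c.vertices - ctr, c.units)
    _, _, theta = principal_axes(out)
    out = out.rotated(np.pi / 2 - theta)
    if polygon_third_moment_y(out.vertices) < 0:
        out = ClosedContour(out.vertices * [1.0, -1.0], c.units)
    return out


def resample_contour(c: ClosedContour, n: int) -> ClosedContour:
    """Resample a contour to ``n`` vertices uniformly by arc length."""
    _check_n(n, 3)
    v = np.vstack([c.vertices, c.vertices[:1]])
    seg = np.hypot(*np.diff(v, axis=0).T)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, v[:, 0])
    y = np.interp(si, s, v[:, 1])
    return ClosedContour(np.column_stack([x, y]), c.units)


def contour_to_csv(c: ClosedContour, path) -> None:
    """Write a contour as a two-column CSV with an ``x,y`` header."""
    np.savetxt(path, c.vertices, delimiter=",", header="x,y", comments="")


def contour_to_svg(c: ClosedContour, path, stroke: str = "black") -> None:
    """Write a contour as a single-path SVG for visual checking."""
    v = c.vertices
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    pad = 0.05 * max(hi - lo)
    d = "M " + " L ".join(f"{x:.6g} {-y:.6g}" for x, y in v) + " Z"
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{lo[0]-pad:.6g} {-hi[1]-pad:.6g} '
        f'{hi[0]-lo[0]+2*pad:.6g} {hi[1]-lo[1]+2*pad:.6g}">'
        f'<path d="{d}" fill="none" stroke="{stroke}" '
        f'stroke-width="{0.005*max(hi-lo):.6g}"/></svg>\n'
    )
    with open(path, "w") as fh:
        fh.write(svg)
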