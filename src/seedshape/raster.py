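"""Binary masks and polygon rasterization.

A ``BinaryMask`` is the unit of measurement and overlap: a boolean raster
with a mm-per-pixel scale.  Polygons are filled by an even-odd scanline rule
evaluated at pixel centers — pixel (row i, col j) has center (x=j, y=i) in
raster coordinates — which is the convention the J-index overlap counts
assume.  Model contours are defined y-up; the y flip into image row order
happens in the model→raster transform, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ClosedContour, ParameterError

__all__ = ["BinaryMask", "fill_polygon", "rasterize", "mask_area_mm2"]


@dataclass
class BinaryMask:
    """Boolean raster of one shape plus its physical scale (mm per pixel)."""

    grid: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ParameterError("mask grid must be 2-D")
        if self.scale <= 0:
            raise ParameterError("scale (mm/px) must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())

    def centroid(self) -> np.ndarray:
        """(row, col) centroid of the foreground pixels."""
        idx = np.nonzero(self.grid)
        if len(idx[0]) == 0:
            raise ParameterError("empty mask has no centroid")
        return np.array([idx[0].mean(), idx[1].mean()])


def fill_polygon(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline fill of a polygon over pixel centers.

    ``xy`` is an (N, 2) array of (col, row) vertices; pixel (i, j) is set
    iff its center (j, i) lies inside the polygon.  Horizontal edges and
    vertices falling exactly on a scanline follow the standard half-open
    rule (an edge covers rows in [min(y), max(y)) ), which keeps crossing
    counts even.
    """
    H, W = shape
    out = np.zeros((H, W), dtype=bool)
    x = np.asarray(xy[:, 0], dtype=float)
    y = np.asarray(xy[:, 1], dtype=float)
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    ylo = np.minimum(y, y2)
    yhi = np.maximum(y, y2)
    r0 = max(0, int(np.ceil(ylo.min())))
    r1 = min(H - 1, int(np.floor(yhi.max())))
    if r1 < r0:
        return out
    rows = np.arange(r0, r1 + 1)
    cross = (rows[None, :] >= ylo[:, None]) & (rows[None, :] < yhi[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rows[None, :] - y[:, None]) / (y2 - y)[:, None]
        xint = x[:, None] + t * (x2 - x)[:, None]
    e_idx, r_idx = np.nonzero(cross)
    if len(e_idx) == 0:
        return out
    xs = xint[e_idx, r_idx]
    order = np.lexsort((xs, r_idx))
    r_sorted = r_idx[order]
    x_sorted = xs[order]
    counts = np.bincount(r_sorted, minlength=len(rows))
    pos = 0
    for k, c in enumerate(counts):
        if c:
            vals = x_sorted[pos:pos + c]
            row = r0 + k
            for m in range(0, c - 1, 2):
                a = max(0, int(np.ceil(vals[m])))
                b = min(W - 1, int(np.ceil(vals[m + 1])) - 1)
                if b >= a:
                    out[row, a:b + 1] = True
            pos += c
    return out


def rasterize(
    contour: ClosedContour,
    shape: tuple[int, int],
    scale: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> BinaryMask:
    """Rasterize a y-up contour onto an image grid.

    ``scale`` is mm (or model units) per pixel; ``origin`` is the (x, y)
    position of the center of the bottom-left pixel.  The y axis is flipped
    into row order: row 0 is the top of the image.
    """
    H, W = shape
    v = contour.vertices
    col = (v[:, 0] - origin[0]) / scale
    row = (H - 1) - (v[:, 1] - origin[1]) / scale
    if col.min() < -0.5 or col.max() > W - 0.5 or row.min() < -0.5 or row.max() > H - 0.5:
        raise ParameterError("contour extends beyond the raster grid")
    return BinaryMask(fill_polygon(np.column_stack([col, row]), shape), scale)


def mask_area_mm2(mask: BinaryMask) -> float:
    return mask.count() * mask.scale**2
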