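"""Seed segmentation, pose normalization and average silhouettes.

The average silhouette of a seed lot is the region where most of the seeds
coincide when their aligned silhouettes are stacked.  Instead of an opacity/
brightness/magic-wand image-editing recipe, the construction here is defined
mathematically: stack pose-normalized binary masks into a per-pixel
*occupancy map* (the fraction of masks covering each pixel) and threshold it
at an occupancy fraction ``theta`` (default 0.9).  This is monotone in
``theta`` and software-independent.

Pose normalization is centroid + principal axis: each seed is centered,
rotated so its moment major axis is vertical, and (optionally) flipped so
the row-mass skewness points downward, which puts the flatter/narrower
hilum end down consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .geometry import ClosedContour, ParameterError
from .raster import BinaryMask

__all__ = [
    "OccupancyMap",
    "AverageSilhouette",
    "segment_seeds",
    "normalize_pose",
    "stack_masks",
    "average_silhouette",
    "mask_to_contour",
]

DEFAULT_THETA = 0.9


class EmptyResultError(ValueError):
    """Segmentation or thresholding produced no foreground."""


class PoseError(ValueError):
    """Mask is degenerate for pose normalization."""


@dataclass
class OccupancyMap:
    """Per-pixel fraction of stacked masks covering that pixel."""

    grid: np.ndarray
    n_masks: int
    scale: float = 1.0

    def mass(self) -> float:
        """Total occupancy times n_masks = summed foreground pixel count."""
        return float(self.grid.sum() * self.n_masks)


@dataclass
class AverageSilhouette:
    """Occupancy-thresholded representative silhouette of a seed lot."""

    mask: BinaryMask
    theta: float
    n_masks: int


# --------------------------------------------------------------------------

def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return img.astype(float)


def segment_seeds(
    image: np.ndarray,
    polarity: str = "dark_on_light",
    min_area_px: int = 50,
    scale: float = 1.0,
    pad_frac: float = 0.1,
) -> list[BinaryMask]:
    """Otsu-threshold an image into one cropped mask per seed.

    Components smaller than ``min_area_px`` are discarded; holes are filled.
    Masks are returned in reading order (top-to-bottom, left-to-right of
    their bounding boxes), each cropped with a ``pad_frac`` margin.
    """
    img = _to_gray(image)
    if np.ptp(img) == 0:
        raise EmptyResultError("image has a single gray level; nothing to segment")
    th = threshold_otsu(img)
    if polarity == "dark_on_light":
        fg = img < th
    elif polarity == "light_on_dark":
        fg = img > th
    else:
        raise ParameterError(f"unknown polarity {polarity!r}")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    masks, boxes = [], []
    slices = ndimage.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        comp = labels[sl] == k
        if comp.sum() < min_area_px:
            continue
        h, w = comp.shape
        pad = int(np.ceil(pad_frac * max(h, w))) + 1
        grid = np.pad(comp, pad)
        masks.append(BinaryMask(grid, scale))
        boxes.append((sl[0].start, sl[1].start))
    if not masks:
        raise EmptyResultError("no components left after area filtering")
    order = np.lexsort(([b[1] for b in boxes], [b[0] for b in boxes]))
    return [masks[i] for i in order]


# --------------------------------------------------------------------------

def _mask_moments(grid: np.ndarray):
    r, c = np.nonzero(grid)
    if len(r) == 0:
        raise PoseError("empty mask")
    ctr = np.array([r.mean(), c.mean()])
    dr, dc = r - ctr[0], c - ctr[1]
    cov = np.array([[np.mean(dr * dr), np.mean(dr * dc)],
                    [np.mean(dr * dc), np.mean(dc * dc)]])
    return ctr, cov


def mask_orientation(grid: np.ndarray) -> float:
    """Angle (radians) of the major principal axis from the row axis."""
    _, cov = _mask_moments(grid)
    lam, vec = np.linalg.eigh(cov)
    v = vec[:, 1]  # major axis, (row, col) components
    ang = np.arctan2(v[1], v[0])  # from row axis toward col axis
    if ang > np.pi / 2:
        ang -= np.pi
    elif ang <= -np.pi / 2:
        ang += np.pi
    return float(ang)


def normalize_pose(mask: BinaryMask, flip_rule: str = "hilum_down") -> BinaryMask:
    """Center a seed mask and rotate its major axis vertical.

    With ``flip_rule="hilum_down"`` the vertical orientation is chosen so the
    row-mass profile's skew tail points up (non-positive third central moment
    in row coordinates), which puts the blunter, flatter hilum end down.
    Rotation is bilinear with re-binarization at 0.5.
    """
    if flip_rule not in ("hilum_down", "none"):
        raise ParameterError(f"unknown flip_rule {flip_rule!r}")
    grid = mask.grid
    ctr, cov = _mask_moments(grid)
    lam = np.linalg.eigvalsh(cov)
    if lam[1] <= 1e-12:
        raise PoseError("degenerate mask: zero second moment")
    # near-isotropic masks (discs): skip rotation, orientation is arbitrary
    if (lam[1] - lam[0]) / lam[1] < 1e-3:
        ang = 0.0
    else:
        ang = mask_orientation(grid)
    r, c = np.nonzero(grid)
    extent = np.hypot(r - ctr[0], c - ctr[1]).max() * 2 + 2
    side = int(np.ceil(extent * 1.1)) | 1  # odd so the center is a pixel
    out_ctr = np.array([(side - 1) / 2.0, (side - 1) / 2.0])
    ca, sa = np.cos(ang), np.sin(ang)
    rot = np.array([[ca, -sa], [sa, ca]])  # output -> input rotation
    offset = ctr - rot @ out_ctr
    rotated = ndimage.affine_transform(
        grid.astype(float), rot, offset=offset, output_shape=(side, side), order=1
    ) >= 0.5
    if not rotated.any():
        raise PoseError("rotation emptied the mask")
    if flip_rule == "hilum_down":
        rows = rotated.sum(axis=1).astype(float)
        i = np.arange(side)
        rbar = (rows * i).sum() / rows.sum()
        mu3 = (rows * (i - rbar) ** 3).sum() / rows.sum()
        if mu3 > 0:
            rotated = rotated[::-1].copy()
    # re-center the centroid on the raster center (integer shift)
    ctr2 = np.array(np.nonzero(rotated)).mean(axis=1)
    shift = np.round(out_ctr - ctr2).astype(int)
    rotated = np.roll(rotated, shift, axis=(0, 1))
    return BinaryMask(rotated, mask.scale)


# --------------------------------------------------------------------------

def stack_masks(masks: list[BinaryMask], margin_frac: float = 0.1) -> OccupancyMap:
    """Average pose-normalized masks into an occupancy map.

    Masks are aligned by integer centroid shifts onto a common grid (largest
    mask plus margin), so total mass is conserved exactly.
    """
    if len(masks) < 2:
        raise ParameterError("need >= 2 masks to stack")
    scales = {m.scale for m in masks}
    if len(scales) > 1:
        raise ParameterError(f"mixed mm/px scales: {sorted(scales)}")
    H = max(m.shape[0] for m in masks)
    W = max(m.shape[1] for m in masks)
    H = int(np.ceil(H * (1 + margin_frac))) | 1
    W = int(np.ceil(W * (1 + margin_frac))) | 1
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    acc = np.zeros((H, W), dtype=float)
    for m in masks:
        canvas = np.zeros((H, W), dtype=bool)
        h, w = m.shape
        ctr = m.centroid()
        r0 = int(np.round(center[0] - ctr[0]))
        c0 = int(np.round(center[1] - ctr[1]))
        if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
            raise ParameterError("mask does not fit the common stacking grid")
        canvas[r0:r0 + h, c0:c0 + w] = m.grid
        acc += canvas
    return OccupancyMap(acc / len(masks), len(masks), masks[0].scale)


def average_silhouette(occ: OccupancyMap, theta: float = DEFAULT_THETA) -> AverageSilhouette:
    """Threshold an occupancy map at fraction ``theta`` (0 < theta <= 1).

    Keeps the largest connected component and fills holes.  Raises if no
    pixel reaches ``theta`` (try a lower threshold).
    """
    if not (0.0 < theta <= 1.0):
        raise ParameterError(f"theta must be in (0, 1], got {theta}")
    sel = occ.grid >= theta - 1e-9
    if not sel.any():
        raise EmptyResultError(
            f"no pixel reaches occupancy {theta}; max is {occ.grid.max():.3f} — lower theta"
        )
    labels, n = ndimage.label(sel)
    if n > 1:
        sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
        sel = labels == (1 + int(np.argmax(sizes)))
    sel = ndimage.binary_fill_holes(sel)
    return AverageSilhouette(BinaryMask(sel, occ.scale), theta, occ.n_masks)


# --------------------------------------------------------------------------

def mask_to_contour(mask: BinaryMask) -> ClosedContour:
    """Sub-pixel boundary polygon of a mask, CCW, in mm (y-up).

    Marching squares at the 0.5 level; for a single-pixel mask the
    convention is a 1-px square centered on that pixel.
    """
    grid = mask.grid
    H = grid.shape[0]
    s = mask.scale
    if grid.sum() == 0:
        raise EmptyResultError("empty mask has no contour")
    if grid.sum() == 1:
        r, c = [int(v[0]) for v in np.nonzero(grid)]
        x, y = c * s, (H - 1 - r) * s
        half = 0.5 * s
        sq = np.array([[x - half, y - half], [x + half, y - half],
                       [x + half, y + half], [x - half, y + half]])
        return ClosedContour(sq, units="mm")
    padded = np.pad(grid.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    longest = max(contours, key=len)
    row = longest[:, 0] - 1.0
    col = longest[:, 1] - 1.0
    x = col * s
    y = (H - 1 - row) * s
    return ClosedContour(np.column_stack([x, y]), units="mm")
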