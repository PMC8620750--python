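"""Synthetic seed photographs with ground truth.

Real seed lots are photographed as 10–30 dark seeds on a light background.
This module emulates such photographs from the geometric model families so
every pipeline stage (segmentation, pose normalization, silhouette
averaging, morphometry, J-index registration) can be exercised against
known ground truth.

Per-seed variation follows the structure seen in real lot tables: length
and width are drawn as *independent* lognormals with the lot's mean and CV
(which reproduces the observed CV(A) ≈ sqrt(CV(L)² + CV(W)²) and the CV of
the aspect ratio), the outline gets band-limited multiplicative radial
noise (preserving star-shapedness), and each seed receives a random
rotation and a grid placement with jitter.  All randomness flows from one
``rng_seed``, so images are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    ClosedContour,
    ParameterError,
    normalize_contour_pose,
    principal_axes,
    polygon_moments,
)
from .morphometry import SeedMeasurements, measure
from .presets import get_model
from .raster import fill_polygon

__all__ = [
    "PopulationSpec",
    "SeedTruth",
    "GroundTruth",
    "perturb_contour",
    "render_population",
    "model_lot_spec",
    "emulate_species",
    "SPECIES_TABLE",
    "DEFAULT_BOUNDARY_NOISE",
]

# Relative radial-noise sd calibrated once so that registered lots score
# J ≈ 90 against their source model (the conventional "good fit" region).
DEFAULT_BOUNDARY_NOISE = 0.08


class GenerationError(RuntimeError):
    pass


class LayoutError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic seed lot.

    Either (``mean_width_mm``, ``cv_width_pct``) or (``mean_ar``,
    ``cv_ar_pct``) fixes the transverse dimension; the width form samples L
    and W independently and is what the species presets use.
    """

    model: str
    n: int = 20
    mean_length_mm: float = 2.7
    cv_length_pct: float = 4.5
    mean_width_mm: float | None = None
    cv_width_pct: float | None = None
    mean_ar: float | None = None
    cv_ar_pct: float | None = None
    boundary_noise: float = DEFAULT_BOUNDARY_NOISE
    noise_harmonics: int = 8
    rotation_range_deg: tuple[float, float] = (0.0, 360.0)
    grid_shape: tuple[int, int] | None = None
    mm_per_px: float = 0.01
    bg_level: float = 235.0
    fg_level: float = 45.0
    pixel_noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("n >= 1 required")
        if self.boundary_noise < 0:
            raise ParameterError("boundary noise amplitude must be >= 0")
        if (self.mean_width_mm is None) == (self.mean_ar is None):
            raise ParameterError("specify exactly one of mean_width_mm or mean_ar")


@dataclass
class SeedTruth:
    """Ground truth for one rendered seed."""

    center_px: tuple[float, float]  # (row, col)
    rotation_deg: float
    length_mm: float
    width_mm: float
    contour_mm: ClosedContour  # noisy contour as placed (image mm frame, y-up)
    clean_contour: ClosedContour  # noise-free scaled contour, pose-normalized
    measurements: SeedMeasurements


@dataclass
class GroundTruth:
    spec: PopulationSpec
    seeds: list[SeedTruth] = field(default_factory=list)


# --------------------------------------------------------------------------

def _lognormal(rng, mean, cv_pct, size=None):
    cv = cv_pct / 100.0
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def perturb_contour(
    c: ClosedContour,
    amplitude: float,
    harmonics: int = 8,
    rng: np.random.Generator | None = None,
) -> ClosedContour:
    """Multiply vertex radii by ``1 + eps(theta)``, eps band-limited noise.

    ``eps`` is a random trigonometric polynomial of order ``harmonics``
    normalized so its sd over the boundary equals ``amplitude``; this keeps
    the outline star-shaped for small amplitudes.  If the result
    self-intersects the draw is retried with the amplitude damped (×0.7, up
    to 5 times).
    """
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    if amplitude == 0:
        return ClosedContour(c.vertices.copy(), c.units)
    rng = np.random.default_rng() if rng is None else rng
    _, ctr, _ = polygon_moments(c.vertices)
    rel = c.vertices - ctr
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    amp = amplitude
    for _ in range(5):
        k = np.arange(1, harmonics + 1)[:, None]
        a = rng.normal(0.0, amp / np.sqrt(harmonics), size=(harmonics, 1))
        b = rng.normal(0.0, amp / np.sqrt(harmonics), size=(harmonics, 1))
        eps = (a * np.cos(k * theta[None, :]) + b * np.sin(k * theta[None, :])).sum(axis=0)
        out = ClosedContour(ctr + rel * (1.0 + eps)[:, None], c.units)
        if out.is_simple():
            return out
        amp *= 0.7
    raise GenerationError("could not draw a simple perturbed contour in 5 attempts")


def _sample_contours(spec: PopulationSpec, rng: np.random.Generator):
    """Per-seed scaled + perturbed contours (pose-normalized frame)."""
    base = get_model(spec.model) if isinstance(spec.model, str) else normalize_contour_pose(spec.model)
    L0, W0, _ = principal_axes(base)
    lengths = _lognormal(rng, spec.mean_length_mm, spec.cv_length_pct, spec.n)
    if spec.mean_width_mm is not None:
        widths = _lognormal(rng, spec.mean_width_mm, spec.cv_width_pct, spec.n)
    else:
        ars = _lognormal(rng, spec.mean_ar, spec.cv_ar_pct, spec.n)
        widths = lengths / ars
    out = []
    for L, W in zip(lengths, widths):
        scaled = ClosedContour(base.vertices * [W / W0, L / L0], units="mm")
        noisy = perturb_contour(scaled, spec.boundary_noise, spec.noise_harmonics, rng)
        out.append((float(L), float(W), scaled, noisy))
    return out


def render_population(spec: PopulationSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a lot as a grayscale photograph plus its ground truth.

    Seeds are placed on a non-overlapping grid (row-major, matching the
    reading order of segmentation) with positional jitter, anti-aliased by
    4× supersampling, over a light background with Gaussian pixel noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _sample_contours(spec, rng)
    mmpp = spec.mm_per_px

    if spec.grid_shape is not None:
        rows, cols = spec.grid_shape
        if rows * cols < spec.n:
            raise LayoutError(f"grid {spec.grid_shape} cannot place {spec.n} seeds")
    else:
        cols = int(np.ceil(np.sqrt(spec.n)))
        rows = int(np.ceil(spec.n / cols))

    diam_px = max(
        np.hypot(*(c.vertices.max(0) - c.vertices.min(0))) / mmpp for *_, c in seeds
    )
    cell = int(np.ceil(diam_px * 1.25)) + 6
    H, W = rows * cell, cols * cell
    alpha = np.zeros((H, W), dtype=float)
    truth = GroundTruth(spec=spec)

    angles = rng.uniform(*spec.rotation_range_deg, size=spec.n)
    jit = rng.uniform(-0.05 * cell, 0.05 * cell, size=(spec.n, 2))
    for i, (L, Wd, clean, noisy) in enumerate(seeds):
        rr, cc = divmod(i, cols)
        center = np.array([rr * cell + cell / 2.0, cc * cell + cell / 2.0]) + jit[i]
        placed = noisy.rotated(np.deg2rad(angles[i]))
        # mm frame of the image: x = col*mmpp, y = (H-1-row)*mmpp
        cx = center[1] * mmpp
        cy = (H - 1 - center[0]) * mmpp
        placed = placed.translated(cx, cy)
        _render_seed(alpha, placed, mmpp)
        truth.seeds.append(
            SeedTruth(
                center_px=(float(center[0]), float(center[1])),
                rotation_deg=float(angles[i]),
                length_mm=L,
                width_mm=Wd,
                contour_mm=placed,
                clean_contour=clean,
                measurements=measure(placed),
            )
        )
    img = spec.bg_level - (spec.bg_level - spec.fg_level) * alpha
    img = img + rng.normal(0.0, spec.pixel_noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


def _render_seed(alpha: np.ndarray, contour_mm: ClosedContour, mmpp: float, ss: int = 4):
    H, W = alpha.shape
    v = contour_mm.vertices
    col = v[:, 0] / mmpp
    row = (H - 1) - v[:, 1] / mmpp
    c0 = max(0, int(np.floor(col.min())) - 2)
    c1 = min(W - 1, int(np.ceil(col.max())) + 2)
    r0 = max(0, int(np.floor(row.min())) - 2)
    r1 = min(H - 1, int(np.ceil(row.max())) + 2)
    h, w = r1 - r0 + 1, c1 - c0 + 1
    # supersampled pixel-center lattice: j_ss = j*ss + (ss-1)/2
    xy = np.column_stack([
        (col - c0) * ss + (ss - 1) / 2.0,
        (row - r0) * ss + (ss - 1) / 2.0,
    ])
    fine = fill_polygon(xy, (h * ss, w * ss))
    block = fine.reshape(h, ss, w, ss).mean(axis=(1, 3))
    np.maximum(alpha[r0:r1 + 1, c0:c1 + 1], block, out=alpha[r0:r1 + 1, c0:c1 + 1])


# --------------------------------------------------------------------------
# species emulation, calibrated to published lot tables
# --------------------------------------------------------------------------

# n, model preset, mean/CV of length and width (mm / %), reference targets
SPECIES_TABLE: dict[str, dict] = {
    "Echinocactus platyacanthus": dict(
        n=153, model="ECHI1", L=2.23, cv_L=3.92, W=1.70, cv_W=4.01,
        targets=dict(A=2.97, cv_A=5.13, AR=1.32, cv_AR=6.11),
    ),
    "Ferocactus herrerae": dict(
        n=121, model="FERO1", L=2.16, cv_L=4.12, W=1.49, cv_W=4.20,
        targets=dict(A=2.54, cv_A=7.87, AR=1.45, cv_AR=2.49),
    ),
    "Hylocereus undatus": dict(
        n=121, model="HYLO1", L=2.69, cv_L=4.43, W=1.44, cv_W=3.87,
        targets=dict(A=3.04, cv_A=5.84, AR=1.87, cv_AR=5.80),
    ),
    "Opuntia ficus-indica": dict(
        n=117, model="OPUNTIA1", L=4.57, cv_L=8.16, W=3.43, cv_W=7.24,
        targets=dict(A=12.34, cv_A=11.39, AR=1.34, cv_AR=10.67),
    ),
    "Pachycereus pringlei": dict(
        n=151, model="PACHY1", L=3.37, cv_L=4.42, W=2.25, cv_W=4.97,
        targets=dict(A=5.95, cv_A=8.22, AR=1.50, cv_AR=4.44),
    ),
    "Pereskia bleo": dict(
        n=13, model="PERESKIA1", L=7.81, cv_L=6.47, W=6.45, cv_W=5.59,
        targets=dict(A=39.61, cv_A=9.67, AR=1.21, cv_AR=6.64),
    ),
}


def model_lot_spec(
    model: str,
    mean_length_mm: float = 2.7,
    cv_length_pct: float = 4.5,
    cv_ar_pct: float = 5.0,
    **overrides,
) -> PopulationSpec:
    """Lot drawn from a model preset keeping its intrinsic aspect ratio.

    Seeds are the model contour under per-seed similarity transforms (size
    lognormal, mild AR jitter) plus boundary noise — the right recipe when
    the lot will be scored with the J index against its own source model.
    """
    contour = get_model(model)
    L, W, _ = principal_axes(contour)
    spec = PopulationSpec(
        model=model,
        mean_length_mm=mean_length_mm,
        cv_length_pct=cv_length_pct,
        mean_ar=L / W,
        cv_ar_pct=cv_ar_pct,
    )
    return replace(spec, **overrides) if overrides else spec


def emulate_species(name: str, **overrides) -> PopulationSpec:
    """Spec whose lot statistics target a published species table row.

    ``overrides`` replace any ``PopulationSpec`` field (e.g. ``n=200`` for
    an oversampled calibration run, or a different ``rng_seed``).
    """
    if name not in SPECIES_TABLE:
        raise ParameterError(
            f"unknown species {name!r}; known: {', '.join(SPECIES_TABLE)}"
        )
    row = SPECIES_TABLE[name]
    spec = PopulationSpec(
        model=row["model"],
        n=row["n"],
        mean_length_mm=row["L"],
        cv_length_pct=row["cv_L"],
        mean_width_mm=row["W"],
        cv_width_pct=row["cv_W"],
    )
    return replace(spec, **overrides) if overrides else spec
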