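"""Seed–model superposition and the J index.

The J index measures the similarity between a seed silhouette and a
geometric model superimposed for maximum similarity:

    J = 100 · S / T

with S the shared (intersection) area and T the total (union) area — i.e.
100 × the Jaccard/IoU similarity of the two regions.  J ranges 0–100 and a
fit above 90 is conventionally considered a good adjustment.

Superposition searches a similarity transform (translation, rotation,
uniform scale, optional mirror) of the model over the seed's pixel grid.
The search is deterministic: moment-based initialization (centroid,
principal axis, area-matching scale, both axis polarities, both mirrors)
followed by Nelder–Mead refinement of (dx, dy, theta, log s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import ClosedContour, ParameterError, normalize_contour_pose, polygon_moments, resample_contour
from .raster import BinaryMask, fill_polygon, rasterize  # noqa: F401  (rasterize re-exported)
from .silhouette import _mask_moments

__all__ = ["SimilarityTransform", "JResult", "j_index_fixed", "register", "batch_j", "rasterize"]

REG_VERTICES = 400  # contour resampling for the inner registration loop


@dataclass(frozen=True)
class SimilarityTransform:
    """Model-to-raster similarity map.

    A model point (x, y) (y-up) maps to raster coordinates
    ``col = dx + s·(x'cosθ − y·sinθ)``, ``row = dy − s·(x'sinθ + y·cosθ)``
    with ``x' = −x`` when mirrored and ``s = exp(log_s)``; the sign flip on
    the row embeds the y-up → row-down image convention.
    """

    dx: float
    dy: float
    theta: float
    log_s: float = 0.0
    mirrored: bool = False

    @property
    def s(self) -> float:
        return float(np.exp(self.log_s))

    def apply(self, vertices: np.ndarray) -> np.ndarray:
        """Map (N, 2) model vertices to (col, row) raster coordinates."""
        x = -vertices[:, 0] if self.mirrored else vertices[:, 0]
        y = vertices[:, 1]
        s, th = self.s, self.theta
        qx = np.cos(th) * x - np.sin(th) * y
        qy = np.sin(th) * x + np.cos(th) * y
        return np.column_stack([self.dx + s * qx, self.dy - s * qy])


@dataclass
class JResult:
    J: float
    S: float
    T: float
    transform: SimilarityTransform | None
    converged: bool = True

    def rounded(self) -> float:
        """J to one decimal, the conventional reporting precision."""
        return round(self.J, 1)


# --------------------------------------------------------------------------

def j_index_fixed(a: BinaryMask, b: BinaryMask) -> JResult:
    """J index of two masks on a common grid, no transform applied."""
    if a.shape != b.shape:
        raise ParameterError(f"masks on different grids: {a.shape} vs {b.shape}")
    S = int(np.count_nonzero(a.grid & b.grid))
    T = int(np.count_nonzero(a.grid | b.grid))
    if T == 0:
        raise ParameterError("both masks are empty; J undefined")
    return JResult(J=100.0 * S / T, S=S, T=T, transform=None)


def _overlap_j(seed_grid: np.ndarray, seed_count: int, model_px: np.ndarray) -> tuple[float, int, int]:
    model_grid = fill_polygon(model_px, seed_grid.shape)
    S = int(np.count_nonzero(seed_grid & model_grid))
    T = seed_count + int(np.count_nonzero(model_grid)) - S
    if T == 0:
        return 0.0, 0, 0
    return 100.0 * S / T, S, T


def register(
    seed: BinaryMask,
    model: ClosedContour,
    allow_scale: bool = True,
    allow_mirror: bool = True,
    maxiter: int = 300,
) -> JResult:
    """Superimpose ``model`` on ``seed`` for maximum J.

    The model is rasterized into the seed's native grid (seed pixels are the
    measured data).  Initialization matches centroids, principal axes (both
    polarities) and areas; a deterministic Nelder–Mead refinement then
    maximizes J over (dx, dy, theta[, log s]) separately for each mirror
    state, so enabling the mirror can never lower the result.
    """
    if seed.count() == 0:
        raise ParameterError("empty seed mask")
    m = normalize_contour_pose(model)
    m = resample_contour(m, min(REG_VERTICES, m.n))
    area_m, _, _ = polygon_moments(m.vertices)
    verts = m.vertices - polygon_moments(m.vertices)[1]

    ctr, cov = _mask_moments(seed.grid)
    lam, vec = np.linalg.eigh(cov)
    vr, vc = vec[:, 1]
    seed_count = seed.count()
    s0 = np.sqrt(seed_count / area_m)
    theta0 = float(np.arctan2(-vc, -vr))

    grid = seed.grid
    best: JResult | None = None
    mirrors = (False, True) if allow_mirror else (False,)
    branches = []
    for mirrored in mirrors:
        starts = []
        for th in (theta0, theta0 + np.pi):
            tr = SimilarityTransform(ctr[1], ctr[0], th, np.log(s0), mirrored)
            j0, _, _ = _overlap_j(grid, seed_count, tr.apply(verts))
            starts.append((j0, tr))
        starts.sort(key=lambda t: -t[0])
        branches.append(starts[0])
    branches.sort(key=lambda t: -t[0])
    for j_init, tr in branches:
        # a branch whose best initialization is far below an already
        # optimized branch cannot plausibly win a local refinement
        if best is not None and j_init < best.J - 10.0:
            continue
        mirrored = tr.mirrored

        if allow_scale:
            x0 = np.array([tr.dx, tr.dy, tr.theta, tr.log_s])
            steps = np.array([2.0, 2.0, 0.05, 0.02])
        else:
            x0 = np.array([tr.dx, tr.dy, tr.theta])
            steps = np.array([2.0, 2.0, 0.05])

        def neg_j(x, mirrored=mirrored):
            t = SimilarityTransform(
                x[0], x[1], x[2],
                x[3] if allow_scale else tr.log_s,
                mirrored,
            )
            j, _, _ = _overlap_j(grid, seed_count, t.apply(verts))
            return -j

        res = _nelder_mead(neg_j, x0, steps, maxiter)
        if res.fun > -99.9:
            # restart with a shrunk simplex to escape pixel-flip plateaus
            res2 = _nelder_mead(neg_j, res.x, steps / 10.0, maxiter // 2)
            if res2.fun < res.fun:
                res = res2
        xb = res.x
        tb = SimilarityTransform(
            xb[0], xb[1], xb[2],
            xb[3] if allow_scale else tr.log_s,
            mirrored,
        )
        j, S, T = _overlap_j(grid, seed_count, tb.apply(verts))
        cand = JResult(J=j, S=S, T=T, transform=tb, converged=bool(res.success))
        if best is None or cand.J > best.J:
            best = cand
    return best


def _nelder_mead(fun, x0, steps, maxiter):
    simplex = np.vstack([x0] + [x0 + np.eye(len(x0))[i] * steps[i] for i in range(len(x0))])
    return optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": 1e-3,
            "fatol": 1e-3,
            "maxiter": maxiter,
            "maxfev": maxiter,
        },
    )


def batch_j(
    seeds: list[BinaryMask],
    model: ClosedContour,
    allow_scale: bool = True,
    allow_mirror: bool = True,
) -> tuple[list[JResult], pd.Series]:
    """Register every seed of a lot against one model.

    Returns the per-seed results and a summary Series (n, mean, sd, min,
    max, cv) of the J values; CV uses the same n−1 convention as the
    morphometry tables.
    """
    from .morphometry import coefficient_of_variation

    if not seeds:
        raise ParameterError("empty seed lot")
    results = [register(s, model, allow_scale, allow_mirror) for s in seeds]
    j = np.array([r.J for r in results])
    summary = pd.Series(
        {
            "n": len(j),
            "mean": j.mean(),
            "sd": j.std(ddof=1) if len(j) > 1 else np.nan,
            "min": j.min(),
            "max": j.max(),
            "cv": coefficient_of_variation(j) if len(j) > 1 else np.nan,
        }
    )
    return results, summary
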