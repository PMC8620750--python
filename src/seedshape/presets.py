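"""Named seed-shape model presets.

Presets live in ``presets.yaml`` next to this module; each maps a name like
``HYLO1`` or ``REBUTIA_HELIOSA`` to a curve family and its published
parameters.  ``get_model`` builds the contour, pose-normalizes it (centroid
at the origin, major axis vertical, hilum end down) and, where the preset
states a target aspect ratio, stretches the minor axis to reach it.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .geometry import (
    BiSemiEllipseParams,
    ClosedContour,
    OpuntiaCurveParams,
    ParameterError,
    SpiralArcParams,
    SuperellipseParams,
    close_arc,
    normalize_contour_pose,
    principal_axes,
    sample_bi_semi_ellipse,
    sample_opuntia_curve,
    sample_spiral_arc,
    sample_superellipse,
    DEFAULT_N,
)

__all__ = ["list_models", "list_all_models", "get_model", "preset_config"]

_FAMILIES = {
    "superellipse": (SuperellipseParams, sample_superellipse),
    "bi_semi_ellipse": (BiSemiEllipseParams, sample_bi_semi_ellipse),
    "spiral_arc": (SpiralArcParams, sample_spiral_arc),
    "opuntia": (OpuntiaCurveParams, sample_opuntia_curve),
}


@lru_cache(maxsize=1)
def _config() -> dict:
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_config(name: str) -> dict:
    cfg = _config()
    entry = cfg["models"].get(name) or cfg.get("extra", {}).get(name)
    if entry is None:
        raise ParameterError(
            f"unknown model preset {name!r}; known: {', '.join(list_all_models())}"
        )
    return entry


def list_models() -> list[str]:
    """Names of the canonical presets."""
    return list(_config()["models"])


def list_all_models() -> list[str]:
    """Canonical plus extra presets."""
    cfg = _config()
    return list(cfg["models"]) + list(cfg.get("extra", {}))


def get_model(name: str, n: int = DEFAULT_N, normalize: bool = True) -> ClosedContour:
    """Build a preset's contour with ``n`` vertices (model units)."""
    entry = preset_config(name)
    cls, sampler = _FAMILIES[entry["family"]]
    params = cls(**entry["params"])
    curve = sampler(params, n)
    if isinstance(curve, ClosedContour):
        contour = curve
    else:
        contour = close_arc(curve, method=entry.get("closure", "chord"))
    if not normalize:
        return contour
    contour = normalize_contour_pose(contour)
    target_ar = entry.get("target_ar")
    if target_ar is not None:
        L, W, _ = principal_axes(contour)
        contour = normalize_contour_pose(contour.scaled((L / target_ar) / W, 1.0))
    return contour
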