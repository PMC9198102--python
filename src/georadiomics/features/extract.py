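"""End-to-end feature extraction and multi-scale ensemble assembly."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import CTVolume
from ..roi import ROIMask
from .discretization import DiscretizationSpec, discretize
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .matrices import texture_matrices
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_NAMES, texture_features

__all__ = [
    "ExtractionSettings",
    "extract_all",
    "build_ensembles",
    "all_feature_names",
    "ENSEMBLE_DEFINITIONS",
]

#: Ensemble feature spaces: name -> tuple of member ROI names (default set).
ENSEMBLE_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "E4SP": ("SP15", "SP20", "SP30", "SP50"),
    "E4CY": ("CY15", "CY20", "CY30", "CY50"),
    "E5CY": ("CY15", "CY20", "CY30", "CY50", "CY50x30"),
    "E9SC": (
        "SP15",
        "SP20",
        "SP30",
        "SP50",
        "CY15",
        "CY20",
        "CY30",
        "CY50",
        "CY50x30",
    ),
}


@dataclass(frozen=True)
class ExtractionSettings:
    """Settings of the feature extractor (defaults match the documented run).

    bin_width: HU width of the fixed-bin gray-level discretization.
    surface_mode: "mesh" (triangulated iso-surface) or "voxel-face".
    """

    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    surface_mode: str = "mesh"

    def as_metadata(self) -> dict:
        return {
            "bin_width_hu": self.discretization.bin_width,
            "surface_mode": self.surface_mode,
            "filters": "none",
            "resampling": "none (index-space distance-1 neighborhoods)",
            "glcm": "symmetric, 13 directions, averaged",
            "zone_connectivity": 26,
        }


def all_feature_names() -> list[str]:
    """The 107 feature names of a single ROI, in canonical order."""
    return [
        *(f"firstorder_{n}" for n in FIRSTORDER_NAMES),
        *(f"shape_{n}" for n in SHAPE_NAMES),
        *TEXTURE_NAMES,
    ]


def _crop_bbox(mask: np.ndarray):
    """Slices of the tight bounding box of a non-empty mask."""
    slices = []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        slices.append(slice(nz[0], nz[-1] + 1))
    return tuple(slices)


def extract_all(
    volume: CTVolume,
    roi: ROIMask,
    settings: ExtractionSettings = ExtractionSettings(),
) -> dict[str, float]:
    """Compute the full 107-feature vector of ``volume`` restricted to ``roi``.

    Feature names are ``<family>_<feature>``; the order is fixed
    (:func:`all_feature_names`).  Deterministic: identical inputs give
    bit-identical vectors.
    """
    mask = np.asarray(roi.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if mask.shape != volume.values.shape:
        raise ValueError("mask and volume shapes differ")

    box = _crop_bbox(mask)
    values = volume.values[box]
    cmask = mask[box]
    spacing = volume.grid.spacing

    out: dict[str, float] = {}
    fo = first_order_features(
        values, cmask, voxel_volume=volume.grid.voxel_volume, disc=settings.discretization
    )
    for name in FIRSTORDER_NAMES:
        out[f"firstorder_{name}"] = fo[name]

    sh = shape_features(cmask, spacing, surface_mode=settings.surface_mode)
    for name in SHAPE_NAMES:
        out[f"shape_{name}"] = sh[name]

    levels, n_levels = discretize(values, cmask, settings.discretization)
    out.update(texture_features(texture_matrices(levels, cmask, n_levels)))
    return out


def build_ensembles(
    per_roi_vectors: dict[str, dict[str, float]],
    definitions: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, dict[str, float]]:
    """Concatenate per-ROI vectors into ensemble feature spaces.

    Feature names are prefixed with their ROI of origin (``SP20_glcm_...``),
    so E4SP has 4 x 107 = 428 features, E5CY 535 and E9SC 963.
    """
    definitions = ENSEMBLE_DEFINITIONS if definitions is None else definitions
    out: dict[str, dict[str, float]] = {}
    for ens_name, members in definitions.items():
        missing = [m for m in members if m not in per_roi_vectors]
        if missing:
            raise KeyError(f"{ens_name}: missing ROI vectors {missing}")
        vec: dict[str, float] = {}
        for m in members:
            for fname, val in per_roi_vectors[m].items():
                vec[f"{m}_{fname}"] = val
        out[ens_name] = vec
    return out
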