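"""Fixed-bin-width gray-level discretization of in-mask HU values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationSpec", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed bin width in HU, anchored at the per-ROI minimum.

    A voxel with value x maps to level ``floor((x - min) / bin_width) + 1``,
    so the lowest in-mask value always lands in level 1.  The default width
    of 25 HU is the conventional CT choice.
    """

    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def discretize(
    values: np.ndarray, mask: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()
) -> tuple[np.ndarray, int]:
    """Discretize in-mask values to integer gray levels >= 1.

    Returns (levels, n_levels) where ``levels`` has the same shape as the
    input with 0 outside the mask, and ``n_levels`` is the highest assigned
    level.  A constant ROI yields a single level.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(values, dtype=float)[mask]
    mn = vals.min()
    lev = np.floor((vals - mn) / spec.bin_width).astype(np.int64) + 1
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = lev
    return levels, int(lev.max())
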