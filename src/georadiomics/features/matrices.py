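"""Texture-matrix builders: GLCM, GLRLM, GLSZM, GLDM and NGTDM.

All matrices are built from the discretized gray-level field (0 outside the
mask) at distance 1 in *index space* (no isotropic resampling).  Directed
neighborhoods use the 13 unique 3D direction vectors (one per +/- pair of the
26-neighborhood); zone/dependence neighborhoods use full 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ANGLES_13", "TextureMatrices", "texture_matrices"]


def _unique_angles() -> tuple[tuple[int, int, int], ...]:
    angles = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if tuple(-c for c in d) in angles:
                    continue
                angles.append(d)
    return tuple(angles)


#: The 13 unique distance-1 direction vectors in 3D (one per +/- pair).
ANGLES_13: tuple[tuple[int, int, int], ...] = _unique_angles()


@dataclass
class TextureMatrices:
    """Raw (unnormalized) texture matrices for one ROI.

    glcm:  (13, Ng, Ng) symmetric pair counts per direction
    glrlm: (13, Ng, max_run) run counts per direction
    glszm: (Ng, max_zone) 26-connected zone counts
    gldm:  (Ng, max_dep) dependence counts (dependence = equal-level
           26-neighbors + 1, so the first column is dependence size 1)
    ngtdm_p: (Ng,) probability of each level among valid voxels
    ngtdm_s: (Ng,) summed |level - mean neighborhood level| per level
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm_p: np.ndarray
    ngtdm_s: np.ndarray
    n_levels: int
    voxel_count: int
    ngtdm_valid_count: int


def _pair_slices(d):
    """Index slices (src, dst) so that arr[src] and arr[dst] are offset by d."""
    src, dst = [], []
    for c in d:
        if c == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif c > 0:
            src.append(slice(None, -c))
            dst.append(slice(c, None))
        else:
            src.append(slice(-c, None))
            dst.append(slice(None, c))
    return tuple(src), tuple(dst)


def _glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    out = np.zeros((len(ANGLES_13), ng, ng), dtype=np.float64)
    for k, d in enumerate(ANGLES_13):
        src, dst = _pair_slices(d)
        a = levels[src]
        b = levels[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        codes = (a[valid] - 1) * ng + (b[valid] - 1)
        counts = np.bincount(codes, minlength=ng * ng).reshape(ng, ng)
        out[k] = counts + counts.T  # symmetric co-occurrences
    return out


def _glrlm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    coords = np.argwhere(mask)
    lev = levels[mask]
    n = len(lev)
    max_len = int(max(mask.shape))
    out = np.zeros((len(ANGLES_13), ng, max_len), dtype=np.float64)
    for k, d in enumerate(ANGLES_13):
        dv = np.asarray(d)
        axis = int(np.flatnonzero(dv)[0])
        t = coords[:, axis] * dv[axis]  # step count along the line
        line = coords - t[:, None] * dv  # line identifier (component `axis` is 0)
        order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
        ts, ls, gs = t[order], line[order], lev[order]
        cont = (
            (ls[1:] == ls[:-1]).all(axis=1)
            & (ts[1:] == ts[:-1] + 1)
            & (gs[1:] == gs[:-1])
        )
        starts = np.flatnonzero(np.concatenate(([True], ~cont)))
        lengths = np.diff(np.append(starts, n))
        np.add.at(out[k], (gs[starts] - 1, lengths - 1), 1.0)
    return out


def _glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    zones: list[tuple[int, np.ndarray]] = []
    max_zone = 1
    for g in range(1, ng + 1):
        binary = levels == g
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.append((g, sizes))
        max_zone = max(max_zone, int(sizes.max()))
    out = np.zeros((ng, max_zone), dtype=np.float64)
    for g, sizes in zones:
        np.add.at(out[g - 1], sizes - 1, 1.0)
    return out


def _gldm(levels: np.ndarray, mask: np.ndarray, ng: int, alpha: float = 0.0) -> np.ndarray:
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in ANGLES_13:
        src, dst = _pair_slices(d)
        a = levels[src]
        b = levels[dst]
        hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[src] += hit
        dep[dst] += hit
    j = dep[mask] + 1  # dependence size counts the center voxel
    g = levels[mask]
    max_dep = int(j.max())
    out = np.zeros((ng, max_dep), dtype=np.float64)
    np.add.at(out, (g - 1, j - 1), 1.0)
    return out


def _ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int):
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in ANGLES_13:
        src, dst = _pair_slices(d)
        a = levels[src]
        b = levels[dst]
        valid = (a > 0) & (b > 0)
        nbr_sum[src] += np.where(valid, b, 0)
        nbr_cnt[src] += valid
        nbr_sum[dst] += np.where(valid, a, 0)
        nbr_cnt[dst] += valid
    has_nbr = mask & (nbr_cnt > 0)
    g = levels[has_nbr].astype(np.float64)
    mean_nbr = nbr_sum[has_nbr] / nbr_cnt[has_nbr]
    n_valid = int(has_nbr.sum())
    p = np.zeros(ng)
    s = np.zeros(ng)
    gi = levels[has_nbr] - 1
    np.add.at(p, gi, 1.0)
    np.add.at(s, gi, np.abs(g - mean_nbr))
    if n_valid > 0:
        p /= n_valid
    return p, s, n_valid


def texture_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> TextureMatrices:
    """Build all five texture matrices from a discretized gray-level field."""
    mask = np.asarray(mask, dtype=bool)
    levels = np.where(mask, levels, 0)
    if n_levels < 1 or not mask.any():
        raise ValueError("empty ROI or invalid gray-level count")
    p, s, n_valid = _ngtdm(levels, mask, n_levels)
    return TextureMatrices(
        glcm=_glcm(levels, n_levels),
        glrlm=_glrlm(levels, mask, n_levels),
        glszm=_glszm(levels, n_levels),
        gldm=_gldm(levels, mask, n_levels),
        ngtdm_p=p,
        ngtdm_s=s,
        n_levels=n_levels,
        voxel_count=int(mask.sum()),
        ngtdm_valid_count=n_valid,
    )
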