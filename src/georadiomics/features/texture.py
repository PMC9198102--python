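"""Texture features from the five matrix families (24+16+16+14+5 = 75).

GLCM and GLRLM features are computed per direction on the normalized matrix
and averaged over the 13 directions.  Degenerate single-level ROIs take the
conventional degenerate values (e.g. GLCM contrast 0, correlation 1) and are
logged, never silently NaN.
"""

from __future__ import annotations

import logging

import numpy as np

from .matrices import TextureMatrices

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "TEXTURE_NAMES",
    "texture_features",
]

logger = logging.getLogger(__name__)

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "MCC",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_NAMES = (
    *(f"glcm_{n}" for n in GLCM_NAMES),
    *(f"glszm_{n}" for n in GLSZM_NAMES),
    *(f"glrlm_{n}" for n in GLRLM_NAMES),
    *(f"gldm_{n}" for n in GLDM_NAMES),
    *(f"ngtdm_{n}" for n in NGTDM_NAMES),
)


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    """Features of one normalized symmetric GLCM (sums to 1)."""
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # marginal over j
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    kd = np.arange(0, ng, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    contrast = float(np.sum(p * (ii - jj) ** 2))
    joint_entropy = float(-np.sum(p * np.log2(p + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    hxy1 = float(-np.sum(p * np.log2(px[:, None] * py[None, :] + _EPS)))
    hxy2 = float(-np.sum(px[:, None] * py[None, :] * np.log2(px[:, None] * py[None, :] + _EPS)))

    if sig_x * sig_y > 0:
        correlation = float((np.sum(p * ii * jj) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0  # single gray level

    imc1 = (joint_entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    # MCC: sqrt of the second largest eigenvalue magnitude of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    if ng > 1:
        q = np.zeros((ng, ng))
        nz = px > 0
        with np.errstate(divide="ignore"):
            w = np.where(py > 0, 1.0 / py, 0.0)
        q[nz] = (p[nz] * w) @ p.T / px[nz, None]
        mags = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, float(mags[-2]))))
    else:
        mcc = 1.0

    diff_avg = float(np.sum(p_diff * kd))
    off = np.abs(ii - jj)
    inv_var_mask = off > 0
    inverse_variance = float(np.sum(p[inv_var_mask] / off[inv_var_mask] ** 2))

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum(p_diff * (kd - diff_avg) ** 2)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "MCC": mcc,
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inverse_variance,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(p_sum * ks)),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _glcm_features(glcm: np.ndarray, ng: int) -> dict[str, float]:
    per_angle = []
    for k in range(glcm.shape[0]):
        total = glcm[k].sum()
        if total == 0:
            continue  # direction with no valid pairs (thin ROI)
        per_angle.append(_glcm_features_one(glcm[k] / total, ng))
    if not per_angle:
        logger.warning("GLCM: no valid voxel pairs in any direction; features set to 0")
        return {n: 0.0 for n in GLCM_NAMES}
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLCM_NAMES}


def _size_matrix_features(
    mat: np.ndarray, names: tuple[str, ...], prefix_map: dict[str, str], n_voxels: int
) -> dict[str, float]:
    """Shared machinery for GLSZM/GLDM-style (level x size) matrices."""
    ng, ns = mat.shape
    nz_total = mat.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ns + 1, dtype=float)[None, :]
    p = mat / nz_total
    pg = p.sum(axis=1)  # marginal over sizes
    ps = p.sum(axis=0)
    mu_g = float(np.sum(p * i))
    mu_s = float(np.sum(p * j))
    ent_p = p[p > 0]
    out = {
        "small": float(np.sum(mat / j**2) / nz_total),
        "large": float(np.sum(mat * j**2) / nz_total),
        "gln": float(np.sum(mat.sum(axis=1) ** 2) / nz_total),
        "glnn": float(np.sum(pg**2)),
        "szn": float(np.sum(mat.sum(axis=0) ** 2) / nz_total),
        "sznn": float(np.sum(ps**2)),
        "pct": float(nz_total / n_voxels),
        "glv": float(np.sum(p * (i - mu_g) ** 2)),
        "sv": float(np.sum(p * (j - mu_s) ** 2)),
        "ent": float(-np.sum(ent_p * np.log2(ent_p + _EPS))),
        "lgl": float(np.sum(mat / i**2) / nz_total),
        "hgl": float(np.sum(mat * i**2) / nz_total),
        "slgl": float(np.sum(mat / (i**2 * j**2)) / nz_total),
        "shgl": float(np.sum(mat * i**2 / j**2) / nz_total),
        "llgl": float(np.sum(mat * j**2 / i**2) / nz_total),
        "lhgl": float(np.sum(mat * i**2 * j**2) / nz_total),
    }
    return {name: out[prefix_map[name]] for name in names}


_GLSZM_MAP = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "szn",
    "SizeZoneNonUniformityNormalized": "sznn",
    "ZonePercentage": "pct",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "sv",
    "ZoneEntropy": "ent",
    "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "slgl",
    "SmallAreaHighGrayLevelEmphasis": "shgl",
    "LargeAreaLowGrayLevelEmphasis": "llgl",
    "LargeAreaHighGrayLevelEmphasis": "lhgl",
}

_GLDM_MAP = {
    "SmallDependenceEmphasis": "small",
    "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "szn",
    "DependenceNonUniformityNormalized": "sznn",
    "GrayLevelVariance": "glv",
    "DependenceVariance": "sv",
    "DependenceEntropy": "ent",
    "LowGrayLevelEmphasis": "lgl",
    "HighGrayLevelEmphasis": "hgl",
    "SmallDependenceLowGrayLevelEmphasis": "slgl",
    "SmallDependenceHighGrayLevelEmphasis": "shgl",
    "LargeDependenceLowGrayLevelEmphasis": "llgl",
    "LargeDependenceHighGrayLevelEmphasis": "lhgl",
}


def _glrlm_features(glrlm: np.ndarray, ng: int, n_voxels: int) -> dict[str, float]:
    per_angle = []
    for k in range(glrlm.shape[0]):
        mat = glrlm[k]
        if mat.sum() == 0:
            continue
        vals = _size_matrix_features(mat, GLSZM_NAMES, _GLSZM_MAP, n_voxels)
        # remap the shared keys onto run-length naming
        per_angle.append(
            {
                "ShortRunEmphasis": vals["SmallAreaEmphasis"],
                "LongRunEmphasis": vals["LargeAreaEmphasis"],
                "GrayLevelNonUniformity": vals["GrayLevelNonUniformity"],
                "GrayLevelNonUniformityNormalized": vals["GrayLevelNonUniformityNormalized"],
                "RunLengthNonUniformity": vals["SizeZoneNonUniformity"],
                "RunLengthNonUniformityNormalized": vals["SizeZoneNonUniformityNormalized"],
                "RunPercentage": vals["ZonePercentage"],
                "GrayLevelVariance": vals["GrayLevelVariance"],
                "RunVariance": vals["ZoneVariance"],
                "RunEntropy": vals["ZoneEntropy"],
                "LowGrayLevelRunEmphasis": vals["LowGrayLevelZoneEmphasis"],
                "HighGrayLevelRunEmphasis": vals["HighGrayLevelZoneEmphasis"],
                "ShortRunLowGrayLevelEmphasis": vals["SmallAreaLowGrayLevelEmphasis"],
                "ShortRunHighGrayLevelEmphasis": vals["SmallAreaHighGrayLevelEmphasis"],
                "LongRunLowGrayLevelEmphasis": vals["LargeAreaLowGrayLevelEmphasis"],
                "LongRunHighGrayLevelEmphasis": vals["LargeAreaHighGrayLevelEmphasis"],
            }
        )
    if not per_angle:
        logger.warning("GLRLM: empty matrices; features set to 0")
        return {n: 0.0 for n in GLRLM_NAMES}
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLRLM_NAMES}


def _ngtdm_features(p: np.ndarray, s: np.ndarray, n_valid: int) -> dict[str, float]:
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p) + 1, dtype=float)
    psum = float(np.sum(p * s))

    coarseness = 1.0 / psum if psum > 0 else 1e6

    if ngp > 1 and n_valid > 0:
        ii = i[present][:, None]
        jj = i[present][None, :]
        pi = p[present][:, None]
        pj = p[present][None, :]
        si = s[present][:, None]
        sj = s[present][None, :]
        contrast = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1)) * np.sum(s) / n_valid
        )
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = psum / busy_den if busy_den > 0 else 0.0
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))) / n_valid
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2)) / np.sum(s) if np.sum(s) > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(m: TextureMatrices) -> dict[str, float]:
    """All 75 texture features, keyed ``<family>_<feature>``."""
    ng = m.n_levels
    out: dict[str, float] = {}
    for name, val in _glcm_features(m.glcm, ng).items():
        out[f"glcm_{name}"] = val
    for name, val in _size_matrix_features(m.glszm, GLSZM_NAMES, _GLSZM_MAP, m.voxel_count).items():
        out[f"glszm_{name}"] = val
    for name, val in _glrlm_features(m.glrlm, ng, m.voxel_count).items():
        out[f"glrlm_{name}"] = val
    for name, val in _size_matrix_features(m.gldm, GLDM_NAMES, _GLDM_MAP, m.voxel_count).items():
        out[f"gldm_{name}"] = val
    for name, val in _ngtdm_features(m.ngtdm_p, m.ngtdm_s, m.ngtdm_valid_count).items():
        out[f"ngtdm_{name}"] = val
    return out
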