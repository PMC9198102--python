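"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops directly from the mathematical
definitions (neighbor walks, flood fills, explicit probability sums) and is
deliberately independent of the vectorized production code it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

# the 13 unique +/- direction pairs: first-encountered member of each pair
DIRECTIONS: list[tuple[int, int, int]] = []
for dx in (-1, 0, 1):
    for dy in (-1, 0, 1):
        for dz in (-1, 0, 1):
            d = (dx, dy, dz)
            if d == (0, 0, 0):
                continue
            if (-dx, -dy, -dz) in DIRECTIONS:
                continue
            DIRECTIONS.append(d)
assert len(DIRECTIONS) == 13

ALL_26 = [d for d in DIRECTIONS] + [(-a, -b, -c) for a, b, c in DIRECTIONS]


def _in_bounds(idx, shape):
    return all(0 <= idx[a] < shape[a] for a in range(3))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """(13, ng, ng) symmetric co-occurrence counts by explicit voxel walks."""
    out = np.zeros((13, ng, ng))
    shape = levels.shape
    for k, d in enumerate(DIRECTIONS):
        for i in np.ndindex(shape):
            if not mask[i]:
                continue
            j = (i[0] + d[0], i[1] + d[1], i[2] + d[2])
            if _in_bounds(j, shape) and mask[j]:
                a, b = levels[i] - 1, levels[j] - 1
                out[k, a, b] += 1
                out[k, b, a] += 1
    return out


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, ng: int, max_len: int) -> np.ndarray:
    """(13, ng, max_len) run counts: walk each line, count maximal runs."""
    out = np.zeros((13, ng, max_len))
    shape = levels.shape
    for k, d in enumerate(DIRECTIONS):
        for i in np.ndindex(shape):
            if not mask[i]:
                continue
            prev = (i[0] - d[0], i[1] - d[1], i[2] - d[2])
            # run starts here iff the previous voxel does not continue it
            if _in_bounds(prev, shape) and mask[prev] and levels[prev] == levels[i]:
                continue
            g = levels[i]
            length = 1
            nxt = (i[0] + d[0], i[1] + d[1], i[2] + d[2])
            while _in_bounds(nxt, shape) and mask[nxt] and levels[nxt] == g:
                length += 1
                nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
            out[k, g - 1, length - 1] += 1
    return out


def brute_glszm(levels: np.ndarray, mask: np.ndarray, ng: int, max_zone: int) -> np.ndarray:
    """(ng, max_zone) zone counts via BFS flood fill with 26-connectivity."""
    out = np.zeros((ng, max_zone))
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    for i in np.ndindex(shape):
        if not mask[i] or seen[i]:
            continue
        g = levels[i]
        size = 0
        queue = deque([i])
        seen[i] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for d in ALL_26:
                n = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in_bounds(n, shape) and mask[n] and not seen[n] and levels[n] == g:
                    seen[n] = True
                    queue.append(n)
        out[g - 1, size - 1] += 1
    return out


def brute_gldm(levels: np.ndarray, mask: np.ndarray, ng: int, max_dep: int) -> np.ndarray:
    """(ng, max_dep) dependence counts; dependence = equal 26-neighbors + 1."""
    out = np.zeros((ng, max_dep))
    shape = levels.shape
    for i in np.ndindex(shape):
        if not mask[i]:
            continue
        dep = 0
        for d in ALL_26:
            n = (i[0] + d[0], i[1] + d[1], i[2] + d[2])
            if _in_bounds(n, shape) and mask[n] and levels[n] == levels[i]:
                dep += 1
        out[levels[i] - 1, dep] += 1  # column dep -> dependence size dep+1
    return out


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int):
    """(p, s, n_valid): occurrence probabilities and neighborhood differences."""
    shape = levels.shape
    p = np.zeros(ng)
    s = np.zeros(ng)
    n_valid = 0
    for i in np.ndindex(shape):
        if not mask[i]:
            continue
        nbrs = []
        for d in ALL_26:
            n = (i[0] + d[0], i[1] + d[1], i[2] + d[2])
            if _in_bounds(n, shape) and mask[n]:
                nbrs.append(levels[n])
        if not nbrs:
            continue
        n_valid += 1
        g = levels[i]
        p[g - 1] += 1
        s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    if n_valid:
        p /= n_valid
    return p, s, n_valid


# ---------------------------------------------------------------------------
# feature-level oracles: direct formula translations with explicit sums


def glcm_features_from_probs(p: np.ndarray) -> dict[str, float]:
    """All 24 GLCM features of one normalized matrix via explicit sums."""
    eps = np.spacing(1.0)
    ng = p.shape[0]
    i_vals = range(1, ng + 1)
    px = [sum(p[i - 1][j - 1] for j in i_vals) for i in i_vals]
    py = [sum(p[i - 1][j - 1] for i in i_vals) for j in i_vals]
    mu_x = sum(i * px[i - 1] for i in i_vals)
    mu_y = sum(j * py[j - 1] for j in i_vals)
    sig_x = math.sqrt(sum(px[i - 1] * (i - mu_x) ** 2 for i in i_vals))
    sig_y = math.sqrt(sum(py[j - 1] * (j - mu_y) ** 2 for j in i_vals))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in i_vals:
        for j in i_vals:
            p_sum[i + j] += p[i - 1][j - 1]
            p_diff[abs(i - j)] += p[i - 1][j - 1]
    hxy = -sum(
        p[i - 1][j - 1] * math.log2(p[i - 1][j - 1] + eps) for i in i_vals for j in i_vals
    )
    hx = -sum(px[i - 1] * math.log2(px[i - 1] + eps) for i in i_vals)
    hy = -sum(py[j - 1] * math.log2(py[j - 1] + eps) for j in i_vals)
    hxy1 = -sum(
        p[i - 1][j - 1] * math.log2(px[i - 1] * py[j - 1] + eps)
        for i in i_vals
        for j in i_vals
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1] + eps)
        for i in i_vals
        for j in i_vals
    )
    da = sum(k * v for k, v in p_diff.items())
    corr = (
        (sum(i * j * p[i - 1][j - 1] for i in i_vals for j in i_vals) - mu_x * mu_y)
        / (sig_x * sig_y)
        if sig_x * sig_y > 0
        else 1.0
    )
    if ng > 1:
        q = np.zeros((ng, ng))
        for i in i_vals:
            for j in i_vals:
                if px[i - 1] == 0:
                    continue
                q[i - 1][j - 1] = sum(
                    p[i - 1][k - 1] * p[j - 1][k - 1] / (px[i - 1] * py[k - 1])
                    for k in i_vals
                    if py[k - 1] > 0
                )
        mags = sorted(abs(v) for v in np.linalg.eigvals(q))
        mcc = math.sqrt(max(0.0, mags[-2]))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": sum(i * j * p[i - 1][j - 1] for i in i_vals for j in i_vals),
        "JointAverage": mu_x,
        "ClusterProminence": sum(
            p[i - 1][j - 1] * (i + j - mu_x - mu_y) ** 4 for i in i_vals for j in i_vals
        ),
        "ClusterShade": sum(
            p[i - 1][j - 1] * (i + j - mu_x - mu_y) ** 3 for i in i_vals for j in i_vals
        ),
        "ClusterTendency": sum(
            p[i - 1][j - 1] * (i + j - mu_x - mu_y) ** 2 for i in i_vals for j in i_vals
        ),
        "Contrast": sum(p[i - 1][j - 1] * (i - j) ** 2 for i in i_vals for j in i_vals),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v + eps) for v in p_diff.values()),
        "DifferenceVariance": sum(v * (k - da) ** 2 for k, v in p_diff.items()),
        "JointEnergy": sum(p[i - 1][j - 1] ** 2 for i in i_vals for j in i_vals),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(
            p[i - 1][j - 1] / (1 + (i - j) ** 2) for i in i_vals for j in i_vals
        ),
        "MCC": mcc,
        "Idmn": sum(
            p[i - 1][j - 1] / (1 + (i - j) ** 2 / ng**2) for i in i_vals for j in i_vals
        ),
        "Id": sum(p[i - 1][j - 1] / (1 + abs(i - j)) for i in i_vals for j in i_vals),
        "Idn": sum(
            p[i - 1][j - 1] / (1 + abs(i - j) / ng) for i in i_vals for j in i_vals
        ),
        "InverseVariance": sum(
            p[i - 1][j - 1] / (i - j) ** 2 for i in i_vals for j in i_vals if i != j
        ),
        "MaximumProbability": max(p[i - 1][j - 1] for i in i_vals for j in i_vals),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * math.log2(v + eps) for v in p_sum.values()),
        "SumSquares": sum(
            p[i - 1][j - 1] * (i - mu_x) ** 2 for i in i_vals for j in i_vals
        ),
    }


def size_matrix_features_naive(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """GLSZM/GLDM/GLRLM-style features of a (level x size) count matrix."""
    eps = np.spacing(1.0)
    ng, ns = mat.shape
    nz = mat.sum()
    out = {}
    out["small"] = sum(mat[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    out["large"] = sum(mat[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    out["gln"] = sum(mat[i].sum() ** 2 for i in range(ng)) / nz
    out["glnn"] = sum(mat[i].sum() ** 2 for i in range(ng)) / nz**2
    out["szn"] = sum(mat[:, j].sum() ** 2 for j in range(ns)) / nz
    out["sznn"] = sum(mat[:, j].sum() ** 2 for j in range(ns)) / nz**2
    out["pct"] = nz / n_voxels
    mu_g = sum((i + 1) * mat[i][j] for i in range(ng) for j in range(ns)) / nz
    mu_s = sum((j + 1) * mat[i][j] for i in range(ng) for j in range(ns)) / nz
    out["glv"] = sum(
        mat[i][j] * (i + 1 - mu_g) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["sv"] = sum(
        mat[i][j] * (j + 1 - mu_s) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["ent"] = -sum(
        (mat[i][j] / nz) * math.log2(mat[i][j] / nz + eps)
        for i in range(ng)
        for j in range(ns)
        if mat[i][j] > 0
    )
    out["lgl"] = sum(mat[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    out["hgl"] = sum(mat[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    out["slgl"] = (
        sum(mat[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)) / nz
    )
    out["shgl"] = (
        sum(mat[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    out["llgl"] = (
        sum(mat[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    out["lhgl"] = (
        sum(mat[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    return out


def ngtdm_features_naive(p: np.ndarray, s: np.ndarray, n_valid: int) -> dict[str, float]:
    present = [i for i in range(len(p)) if p[i] > 0]
    ngp = len(present)
    psum = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / psum if psum > 0 else 1e6
    if ngp > 1 and n_valid > 0:
        contrast = (
            sum(
                p[i] * p[j] * ((i + 1) - (j + 1)) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
            * sum(s)
            / n_valid
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = psum / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / n_valid
        )
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / sum(s)
            if sum(s) > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def first_order_naive(x: np.ndarray, voxel_volume: float, bin_width: float) -> dict[str, float]:
    """Independent first-order formulas (scipy for skewness/kurtosis)."""
    from scipy import stats

    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    lev = np.floor((x - x.min()) / bin_width).astype(int)
    counts = np.bincount(lev)
    probs = counts[counts > 0] / n
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    var = float(np.var(x))
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(stats.entropy(probs, base=2)),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(np.ptp(x)),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - x.mean()))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(stats.skew(x, bias=True)) if var > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, bias=True, fisher=False)) if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((probs**2).sum()),
    }
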