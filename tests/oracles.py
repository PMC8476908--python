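"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops directly from the defining
formulas, sharing no code with the package implementation, so agreement
is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)


# -- sliding-window SSIM ---------------------------------------------------

def naive_ssim_maps(x, y, window=11, k1=0.01, k2=0.03, L=200.0):
    """Double-loop SSIM decomposition with symmetric (reflect) padding.

    Returns (luminance, contrast, structure, combined) maps.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    c3 = c2 / 2.0
    pad = window // 2
    xp = np.pad(x, pad, mode="symmetric")
    yp = np.pad(y, pad, mode="symmetric")
    h, w = x.shape
    lum = np.empty((h, w))
    con = np.empty((h, w))
    stru = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            wx = xp[i : i + window, j : j + window]
            wy = yp[i : i + window, j : j + window]
            mx, my = wx.mean(), wy.mean()
            vx = (wx * wx).mean() - mx * mx
            vy = (wy * wy).mean() - my * my
            sx = math.sqrt(max(vx, 0.0))
            sy = math.sqrt(max(vy, 0.0))
            cov = (wx * wy).mean() - mx * my
            lum[i, j] = (2 * mx * my + c1) / (mx * mx + my * my + c1)
            con[i, j] = (2 * sx * sy + c2) / (sx * sx + sy * sy + c2)
            stru[i, j] = (cov + c3) / (sx * sy + c3)
    return lum, con, stru, lum * con * stru


# -- gray-level matrices by enumeration ------------------------------------

def glcm_counts(lv, ng, offset):
    """Symmetric co-occurrence counts by explicit pixel-pair enumeration."""
    dr, dc = offset
    h, w = lv.shape
    p = np.zeros((ng, ng))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w:
                p[lv[i, j] - 1, lv[i2, j2] - 1] += 1
                p[lv[i2, j2] - 1, lv[i, j] - 1] += 1
    return p


def glcm_features(lv, ng):
    """All 24 co-occurrence features, averaged over the four directions."""
    feats = []
    for off in ((0, 1), (1, 1), (1, 0), (1, -1)):
        counts = glcm_counts(lv, ng, off)
        p = counts / counts.sum()
        feats.append(_glcm_from_p(p))
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


def _glcm_from_p(p):
    ng = p.shape[0]
    out = {}
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum(px[i] * ((i + 1) - mux) ** 2 for i in range(ng)))
    sy = math.sqrt(sum(py[j] * ((j + 1) - muy) ** 2 for j in range(ng)))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]

    out["Autocorrelation"] = sum(
        p[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    out["JointAverage"] = mux
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3),
                        ("ClusterTendency", 2)):
        out[name] = sum(
            p[i, j] * ((i + 1) + (j + 1) - mux - muy) ** power
            for i in range(ng) for j in range(ng)
        )
    out["Contrast"] = sum(
        p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
    )
    out["Correlation"] = (
        (out["Autocorrelation"] - mux * muy) / (sx * sy) if sx * sy > 0 else 1.0
    )
    da = sum(k * v for k, v in pdiff.items())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * math.log2(v + EPS) for v in pdiff.values())
    out["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    out["JointEnergy"] = sum(
        p[i, j] ** 2 for i in range(ng) for j in range(ng)
    )
    hxy = -sum(
        p[i, j] * math.log2(p[i, j] + EPS) for i in range(ng) for j in range(ng)
    )
    out["JointEntropy"] = hxy
    hx = -sum(v * math.log2(v + EPS) for v in px)
    hy = -sum(v * math.log2(v + EPS) for v in py)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j] + EPS)
        for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
        for i in range(ng) for j in range(ng)
    )
    out["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["Idm"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["Idmn"] = sum(
        p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    out["Id"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["Idn"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["MaximumProbability"] = p.max()
    out["SumAverage"] = sum(k * v for k, v in psum.items())
    out["SumEntropy"] = -sum(v * math.log2(v + EPS) for v in psum.values())
    out["SumSquares"] = sum(
        p[i, j] * ((i + 1) - mux) ** 2 for i in range(ng) for j in range(ng)
    )
    if ng > 1:
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                q[i, j] = sum(
                    p[i, k] * p[j, k] / ((px[i] + EPS) * (py[k] + EPS))
                    for k in range(ng)
                )
        eigs = sorted(abs(np.linalg.eigvals(q)))
        out["MCC"] = math.sqrt(max(0.0, eigs[-2]))
    else:
        out["MCC"] = 1.0
    return out


def weighted_family(cells, n_pixels):
    """Shared run/zone/dependence feature family from (i, j, count) cells."""
    ns = sum(c for _, _, c in cells)
    pg = {}
    ps = {}
    for i, j, c in cells:
        pg[i] = pg.get(i, 0.0) + c
        ps[j] = ps.get(j, 0.0) + c
    mu_i = sum(c / ns * i for i, j, c in cells)
    mu_j = sum(c / ns * j for i, j, c in cells)
    return {
        "SmallEmphasis": sum(c / j**2 for i, j, c in cells) / ns,
        "LargeEmphasis": sum(c * j**2 for i, j, c in cells) / ns,
        "GrayLevelNonUniformity": sum(v**2 for v in pg.values()) / ns,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in pg.values()) / ns**2,
        "SizeNonUniformity": sum(v**2 for v in ps.values()) / ns,
        "SizeNonUniformityNormalized": sum(v**2 for v in ps.values()) / ns**2,
        "Percentage": ns / n_pixels,
        "GrayLevelVariance": sum(c / ns * (i - mu_i) ** 2 for i, j, c in cells),
        "SizeVariance": sum(c / ns * (j - mu_j) ** 2 for i, j, c in cells),
        "Entropy": -sum(c / ns * math.log2(c / ns + EPS) for i, j, c in cells),
        "LowGrayLevelEmphasis": sum(c / i**2 for i, j, c in cells) / ns,
        "HighGrayLevelEmphasis": sum(c * i**2 for i, j, c in cells) / ns,
        "SmallLowGrayLevelEmphasis": sum(c / (i * j) ** 2 for i, j, c in cells) / ns,
        "SmallHighGrayLevelEmphasis": sum(c * i**2 / j**2 for i, j, c in cells) / ns,
        "LargeLowGrayLevelEmphasis": sum(c * j**2 / i**2 for i, j, c in cells) / ns,
        "LargeHighGrayLevelEmphasis": sum(c * (i * j) ** 2 for i, j, c in cells) / ns,
    }


def run_cells(lv, direction):
    """Maximal runs (gray, length) by walking every line start."""
    h, w = lv.shape
    dr, dc = direction
    counts = {}
    for i in range(h):
        for j in range(w):
            pi, pj = i - dr, j - dc
            if 0 <= pi < h and 0 <= pj < w and lv[pi, pj] == lv[i, j]:
                continue  # not a run start
            length = 1
            ci, cj = i + dr, j + dc
            while 0 <= ci < h and 0 <= cj < w and lv[ci, cj] == lv[i, j]:
                length += 1
                ci, cj = ci + dr, cj + dc
            key = (int(lv[i, j]), length)
            counts[key] = counts.get(key, 0) + 1
    return [(i, j, c) for (i, j), c in sorted(counts.items())]


def glrlm_features(lv, ng):
    per = [
        weighted_family(run_cells(lv, d), lv.size)
        for d in ((0, 1), (1, 1), (1, 0), (1, -1))
    ]
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


def zone_cells(lv):
    """8-connected equal-value zones by explicit flood fill."""
    h, w = lv.shape
    seen = np.zeros((h, w), dtype=bool)
    counts = {}
    for i in range(h):
        for j in range(w):
            if seen[i, j]:
                continue
            val = lv[i, j]
            stack = [(i, j)]
            seen[i, j] = True
            size = 0
            while stack:
                ci, cj = stack.pop()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = ci + di, cj + dj
                        if (
                            0 <= ni < h and 0 <= nj < w
                            and not seen[ni, nj] and lv[ni, nj] == val
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            key = (int(val), size)
            counts[key] = counts.get(key, 0) + 1
    return [(i, j, c) for (i, j), c in sorted(counts.items())]


def glszm_features(lv, ng):
    return weighted_family(zone_cells(lv), lv.size)


def dependence_cells(lv, alpha=0):
    h, w = lv.shape
    counts = {}
    for i in range(h):
        for j in range(w):
            dep = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and abs(
                        int(lv[ni, nj]) - int(lv[i, j])
                    ) <= alpha:
                        dep += 1
            key = (int(lv[i, j]), dep + 1)
            counts[key] = counts.get(key, 0) + 1
    return [(i, j, c) for (i, j), c in sorted(counts.items())]


def gldm_features(lv, ng):
    return weighted_family(dependence_cells(lv), lv.size)


def ngtdm_features(lv, ng):
    h, w = lv.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for i in range(h):
        for j in range(w):
            nbrs = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w:
                        nbrs.append(float(lv[ni, nj]))
            lvl = int(lv[i, j]) - 1
            n_i[lvl] += 1
            s_i[lvl] += abs(lv[i, j] - sum(nbrs) / len(nbrs))
    n_pix = n_i.sum()
    p_i = n_i / n_pix
    present = [k for k in range(ng) if n_i[k] > 0]
    ngp = len(present)
    denom = sum(p_i[k] * s_i[k] for k in present)
    coarseness = 1.0 / denom if denom > 0 else 1.0e6
    if ngp > 1:
        contrast = (
            sum(
                p_i[a] * p_i[b] * (a - b) ** 2
                for a in present for b in present
            ) / (ngp * (ngp - 1))
            * sum(s_i[k] for k in present) / n_pix
        )
    else:
        contrast = 0.0
    busy_den = sum(
        abs((a + 1) * p_i[a] - (b + 1) * p_i[b])
        for a in present for b in present
    )
    busyness = denom / busy_den if busy_den > 0 else 0.0
    complexity = (
        sum(
            abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
            for a in present for b in present
        ) / n_pix
    )
    s_sum = sum(s_i[k] for k in present)
    strength = (
        sum(
            (p_i[a] + p_i[b]) * (a - b) ** 2
            for a in present for b in present
        ) / s_sum
        if s_sum > 0
        else 0.0
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# -- ROC / AUC -------------------------------------------------------------

def auc_pair_counting(truth, scores):
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for t, s in zip(truth, scores) if t]
    neg = [s for t, s in zip(truth, scores) if not t]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
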