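"""Radiomics feature extraction from comparison maps.

Ninety-four features per map, from six families:

* first-order intensity statistics (19),
* gray level co-occurrence matrix, GLCM (24),
* gray level dependence matrix, GLDM (14),
* gray level run length matrix, GLRLM (16),
* gray level size zone matrix, GLSZM (16),
* neighbouring gray tone difference matrix, NGTDM (5).

Definitions follow the IBSI-aligned formulations used by the standard
radiomics extraction libraries.  Texture families are computed on a
discretized copy of the map (fixed bin width or fixed bin count), in 2D,
with distance-1 offsets; GLCM and GLRLM use the four 2D directions
(0/45/90/135 degrees), symmetric counting, and feature values averaged
over directions.  Shape families are deliberately absent: the analysed
maps all share one rectangular support, so shape features carry no
information here.

Degenerate inputs (e.g. a constant map) yield the defined limiting
values — GLCM contrast 0, correlation 1, coarseness capped — never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label

from .core import FluenceMap, as_pixels

_EPS = np.spacing(1.0)

#: Cap returned by NGTDM coarseness for a perfectly uniform image.
COARSENESS_CAP = 1.0e6

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
]
GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def feature_names() -> list[str]:
    """The 94 canonical ``family_Feature`` names, in extraction order."""
    out = [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    out += [f"glcm_{n}" for n in GLCM_NAMES]
    out += [f"gldm_{n}" for n in GLDM_NAMES]
    out += [f"glrlm_{n}" for n in GLRLM_NAMES]
    out += [f"glszm_{n}" for n in GLSZM_NAMES]
    out += [f"ngtdm_{n}" for n in NGTDM_NAMES]
    assert len(out) == 94
    return out


@dataclass(frozen=True)
class DiscretizationConfig:
    """Gray-level discretization for the texture families.

    ``method="width"`` bins with a fixed ``bin_width`` anchored at the map
    minimum (difference-based texture features are then invariant to
    adding a constant); ``method="count"`` uses ``bin_count`` equal-width
    bins over the map's range.
    """

    method: Literal["width", "count"] = "width"
    bin_width: float = 25.0
    bin_count: int = 32

    def __post_init__(self) -> None:
        if self.method == "width" and self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.method == "count" and self.bin_count < 2:
            raise ValueError("bin count must be >= 2")


def discretize(image: np.ndarray, cfg: DiscretizationConfig) -> np.ndarray:
    """Map intensities to integer gray levels starting at 1."""
    x = np.asarray(image, dtype=np.float64)
    lo = float(x.min())
    if cfg.method == "width":
        lv = np.floor((x - lo) / cfg.bin_width).astype(np.int64) + 1
    else:
        rng = float(x.max()) - lo
        if rng <= 0:
            return np.ones(x.shape, dtype=np.int64)
        width = rng / cfg.bin_count
        lv = np.minimum(
            np.floor((x - lo) / width).astype(np.int64), cfg.bin_count - 1
        ) + 1
    return lv


def center_crop(image: FluenceMap | np.ndarray, side: int = 512) -> np.ndarray:
    """Centered ``side x side`` submatrix.

    For odd residuals the extra margin goes to the bottom/right: the
    offset is ``floor((H - side) / 2)`` on each axis.
    """
    x = as_pixels(image)
    h, w = x.shape
    if h < side or w < side:
        raise ValueError(f"map {h}x{w} is smaller than the {side}x{side} crop")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return x[r0 : r0 + side, c0 : c0 + side]


# -- first order -----------------------------------------------------------

def _firstorder(x: np.ndarray, lv: np.ndarray) -> dict[str, float]:
    flat = x.ravel()
    n = flat.size
    mean = float(flat.mean())
    # single centring pass feeds variance, higher moments and deviations
    d = flat - mean
    d2 = d * d
    var = float(d2.mean())
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(flat, [10, 25, 50, 75, 90])
    robust = flat[(flat >= p10) & (flat <= p90)]
    hist = np.bincount(lv.ravel() - 1)
    p = hist[hist > 0] / n
    if var > 0:
        skew = float((d2 * d).mean() / var**1.5)
        kurt = float((d2 * d2).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0
    energy = float(np.dot(flat, flat))
    vmin, vmax = float(flat.min()), float(flat.max())
    return {
        "Energy": energy,
        "TotalEnergy": energy,  # unit pixel area
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": vmin,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": vmax,
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": vmax - vmin,
        "MeanAbsoluteDeviation": float(np.abs(d).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }


# -- GLCM ------------------------------------------------------------------

_OFFSETS_4 = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_matrix(lv: np.ndarray, ng: int, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one distance-1 offset."""
    dr, dc = offset
    h, w = lv.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = lv[r0, c0].ravel() - 1
    b = lv[r1, c1].ravel() - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
    return counts + counts.T


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    autoc = float(np.sum(p * ii * jj))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    if sig_x * sig_y > 0:
        corr = float((autoc - mu_x * mu_y) / (sig_x * sig_y))
    else:
        corr = 1.0
    diff_avg = float(np.sum(k_diff * p_diff))

    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    hxy = float(-np.sum(p * np.log2(p + _EPS)))
    pxy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxy + _EPS)))
    hxy2 = float(-np.sum(pxy * np.log2(pxy + _EPS)))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = ii != jj
    inv_var = float(np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    if ng > 1:
        q = (p / (px[:, None] + _EPS)) @ (p / (py[None, :] + _EPS)).T
        eigs = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eigs[-2])))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
        "MCC": mcc,
    }


def _glcm(lv: np.ndarray, ng: int) -> dict[str, float]:
    per_angle = []
    for off in _OFFSETS_4:
        counts = glcm_matrix(lv, ng, off)
        total = counts.sum()
        if total == 0:  # degenerate 1-pixel-wide input
            continue
        per_angle.append(_glcm_features_single(counts / total))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_NAMES}


# -- GLRLM -----------------------------------------------------------------

def _rle_lines(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a 1D array; runs of value 0 (separators) dropped."""
    change = np.nonzero(np.diff(arr))[0]
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [arr.size])))
    values = arr[starts]
    keep = values > 0
    return values[keep], lengths[keep]


def _diag_lines(lv: np.ndarray) -> np.ndarray:
    """Flatten all anti-diagonals (direction (1,-1)) into one separated array."""
    h, w = lv.shape
    # shear: row r shifted right by r, so columns become anti-diagonals;
    # the extra all-zero row puts a separator at the end of every column
    # after the transpose (zeros never collide with gray levels >= 1)
    sheared = np.zeros((h + 1, w + h), dtype=lv.dtype)
    for r in range(h):
        sheared[r, r : r + w] = lv[r]
    return sheared.T.ravel()


def glrlm_matrix(lv: np.ndarray, ng: int, direction: tuple[int, int]) -> np.ndarray:
    """Run-length count matrix P[i, j-1] for one of the 4 directions."""
    h, w = lv.shape
    values, lengths = _rle_lines(_run_lines(lv, direction))
    max_len = max(h, w)
    counts = np.bincount(
        (values - 1) * max_len + (lengths - 1), minlength=ng * max_len
    )
    return counts.reshape(ng, max_len)


def _pair_counts(i: np.ndarray, j: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate (gray, size) observations into distinct cells with counts."""
    m = int(j.max()) + 1
    key = i.astype(np.int64) * m + j.astype(np.int64)
    ku, counts = np.unique(key, return_counts=True)
    return ku // m, ku % m, counts.astype(np.float64)


def _weighted_features_sparse(
    i: np.ndarray, j: np.ndarray, c: np.ndarray, n_pixels: int
) -> dict[str, float]:
    """The shared size/length-weighted feature family over matrix cells.

    ``(i, j, c)`` are the non-zero cells of the count matrix: gray level,
    size/length (both 1-based) and count.  Produces the 14/16-feature
    family shared by GLRLM (runs), GLSZM (zones) and GLDM (dependencies);
    callers rename to family conventions.  Sparse on purpose: zone sizes
    can reach the pixel count, so a dense matrix may be huge while its
    occupied cells stay few.
    """
    i = i.astype(np.float64)
    j = j.astype(np.float64)
    ns = float(c.sum())
    p = c / ns
    pg = np.bincount(i.astype(np.int64), weights=c)  # per gray level
    _ju, jinv = np.unique(j, return_inverse=True)
    ps = np.bincount(jinv, weights=c)  # per size
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    return {
        "SmallEmphasis": float(np.sum(c / j**2) / ns),
        "LargeEmphasis": float(np.sum(c * j**2) / ns),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / ns**2),
        "SizeNonUniformity": float(np.sum(ps**2) / ns),
        "SizeNonUniformityNormalized": float(np.sum(ps**2) / ns**2),
        "Percentage": float(ns / n_pixels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "SizeVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(c / i**2) / ns),
        "HighGrayLevelEmphasis": float(np.sum(c * i**2) / ns),
        "SmallLowGrayLevelEmphasis": float(np.sum(c / (i**2 * j**2)) / ns),
        "SmallHighGrayLevelEmphasis": float(np.sum(c * i**2 / j**2) / ns),
        "LargeLowGrayLevelEmphasis": float(np.sum(c * j**2 / i**2) / ns),
        "LargeHighGrayLevelEmphasis": float(np.sum(c * i**2 * j**2) / ns),
    }


def _weighted_matrix_features(p_mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    """Dense-matrix entry point to :func:`_weighted_features_sparse`."""
    ii, jj = np.nonzero(p_mat)
    return _weighted_features_sparse(ii + 1, jj + 1, p_mat[ii, jj], n_pixels)


_GLRLM_RENAME = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}

_GLSZM_RENAME = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}

_GLDM_RENAME = {
    "SmallDependenceEmphasis": "SmallEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


def _run_lines(lv: np.ndarray, direction: tuple[int, int]) -> np.ndarray:
    h, w = lv.shape
    if direction == (0, 1):
        return np.hstack([lv, np.zeros((h, 1), dtype=lv.dtype)]).ravel()
    if direction == (1, 0):
        return np.hstack([lv.T, np.zeros((w, 1), dtype=lv.dtype)]).ravel()
    if direction == (1, -1):
        return _diag_lines(lv)
    if direction == (1, 1):
        return _diag_lines(lv[:, ::-1])
    raise ValueError(f"unsupported direction {direction}")


def _glrlm(lv: np.ndarray, ng: int) -> dict[str, float]:
    n = lv.size
    per_dir = []
    for direction in ((0, 1), (1, 1), (1, 0), (1, -1)):
        values, lengths = _rle_lines(_run_lines(lv, direction))
        per_dir.append(
            _weighted_features_sparse(*_pair_counts(values, lengths), n)
        )
    return {
        name: float(np.mean([f[key] for f in per_dir]))
        for name, key in _GLRLM_RENAME.items()
    }


# -- GLSZM -----------------------------------------------------------------

def glszm_matrix(lv: np.ndarray, ng: int) -> np.ndarray:
    """Zone count matrix P[i, s-1]: 8-connected zones of equal gray level.

    Dense form, for inspection and small-matrix testing; the extraction
    path works from the sparse zone list directly.
    """
    grays, sizes = _zone_sizes_grays(lv)
    max_size = int(sizes.max())
    counts = np.bincount(
        (grays - 1) * max_size + (sizes - 1), minlength=ng * max_size
    )
    return counts.reshape(ng, max_size)


def _zone_sizes_grays(lv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-zone (gray level, size) for all 8-connected equal-value zones."""
    labels = _cc_label(lv, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    _, first = np.unique(labels.ravel(), return_index=True)
    if 0 in labels:
        first = first[1:]
    grays = lv.ravel()[first]
    return grays, sizes


def _glszm(lv: np.ndarray, ng: int) -> dict[str, float]:
    grays, sizes = _zone_sizes_grays(lv)
    feats = _weighted_features_sparse(*_pair_counts(grays, sizes), lv.size)
    return {name: feats[key] for name, key in _GLSZM_RENAME.items()}


# -- GLDM ------------------------------------------------------------------

def gldm_matrix(lv: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P[i, j-1], j = 1 + #dependent neighbours.

    A Chebyshev-distance-1 neighbour is dependent when its gray level
    differs from the centre by at most ``alpha``.  Neighbours outside the
    image do not count.
    """
    h, w = lv.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)):
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        dep[r0, c0] += np.abs(lv[r0, c0] - lv[r1, c1]) <= alpha
    j = dep + 1  # dependence size includes the centre pixel
    max_j = int(j.max())
    counts = np.bincount(
        (lv.ravel() - 1) * max_j + (j.ravel() - 1), minlength=ng * max_j
    )
    return counts.reshape(ng, max_j)


def _gldm(lv: np.ndarray, ng: int) -> dict[str, float]:
    feats = _weighted_matrix_features(gldm_matrix(lv, ng), lv.size)
    return {name: feats[key] for name, key in _GLDM_RENAME.items()}


# -- NGTDM -----------------------------------------------------------------

def ngtdm_table(lv: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-gray-level counts n_i and summed absolute differences s_i.

    s_i sums |i - mean of the 8-neighbourhood| over pixels of level i,
    with edge neighbourhoods averaged over the neighbours that exist.
    """
    x = lv.astype(np.float64)
    k = np.ones((3, 3))
    k[1, 1] = 0.0
    nbr_sum = ndimage.correlate(x, k, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(np.ones_like(x), k, mode="constant", cval=0.0)
    a_bar = nbr_sum / nbr_cnt
    diff = np.abs(x - a_bar)
    n_i = np.bincount(lv.ravel() - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(lv.ravel() - 1, weights=diff.ravel(), minlength=ng)
    return n_i, s_i


def _ngtdm(lv: np.ndarray, ng: int) -> dict[str, float]:
    n_i, s_i = ngtdm_table(lv, ng)
    n_pix = float(n_i.sum())
    p_i = n_i / n_pix
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP

    pi_v, ii_v, si_v = p_i[present], i[present], s_i[present]
    d_ij2 = (ii_v[:, None] - ii_v[None, :]) ** 2
    pp = pi_v[:, None] * pi_v[None, :]
    if ngp > 1:
        contrast = float(np.sum(pp * d_ij2) / (ngp * (ngp - 1)) * np.sum(si_v) / n_pix)
    else:
        contrast = 0.0

    busy_den = float(np.sum(np.abs(ii_v[:, None] * pi_v[:, None] - ii_v[None, :] * pi_v[None, :])))
    busyness = float(np.sum(pi_v * si_v) / busy_den) if busy_den > 0 else 0.0

    psum = pi_v[:, None] + pi_v[None, :]
    pschg = pi_v[:, None] * si_v[:, None] + pi_v[None, :] * si_v[None, :]
    complexity = float(np.sum(np.sqrt(d_ij2) * pschg / psum) / n_pix)

    s_sum = float(np.sum(si_v))
    strength = float(np.sum(psum * d_ij2) / s_sum) if s_sum > 0 else 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# -- public API ------------------------------------------------------------

def extract_features(
    image: FluenceMap | np.ndarray,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """Extract the 94 features from one 2D map.

    Returns an ordered ``name -> value`` mapping with the canonical
    ``family_Feature`` names.  All values are finite.
    """
    cfg = cfg or DiscretizationConfig()
    x = as_pixels(image)
    if not np.all(np.isfinite(x)):
        raise ValueError("map contains non-finite values")
    lv = discretize(x, cfg)
    ng = int(lv.max())

    out: dict[str, float] = {}
    for fam, feats in (
        ("firstorder", _firstorder(x, lv)),
        ("glcm", _glcm(lv, ng)),
        ("gldm", _gldm(lv, ng)),
        ("glrlm", _glrlm(lv, ng)),
        ("glszm", _glszm(lv, ng)),
        ("ngtdm", _ngtdm(lv, ng)),
    ):
        for name, value in feats.items():
            out[f"{fam}_{name}"] = float(value)
    assert len(out) == 94
    return out


#: map-type name -> feature-source maps for each ML input configuration
ML_CONFIG_SOURCES: dict[str, tuple[str, ...]] = {
    "ml1": ("dd",),
    "ml2": ("luminance", "contrast", "structure"),
    "ml3": ("dd", "luminance", "contrast", "structure"),
}


def select_ml_columns(columns: Iterable[str], ml_config: str) -> list[str]:
    """Feature columns belonging to one ML input configuration."""
    sources = ML_CONFIG_SOURCES[ml_config.lower()]
    return [c for c in columns if c.split("_", 1)[0] in sources]


def build_feature_matrix(cohort, ml_config: str = "ml3", **kwargs):
    """Feature matrix over a cohort; see :func:`.pipeline.build_feature_matrix`."""
    from .pipeline import build_feature_matrix as _impl

    return _impl(cohort, ml_config, **kwargs)
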