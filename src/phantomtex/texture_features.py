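"""The 41 texture features: histogram, GLCM, GLRL, GLGM, and Laws families.

Per slice-ROI the extractor computes 12 first-order (histogram) features, 5
gray-level co-occurrence matrix (GLCM) features, 11 gray-level run-length
(GLRL) features, 4 gray-level gradient matrix (GLGM) features, and 9 Laws
texture-energy features, plus three report extras (intensity skewness,
intensity kurtosis, and the sum of the Laws features).

Conventions fixed here (configurable via :class:`FeatureConfig`):

* Gray levels are obtained by linear min-max binning of the masked,
  normalized intensities into G = 256 levels.
* GLCM and GLRL use the four distance-1 directions (horizontal, 45 degrees,
  vertical, 135 degrees).  GLCM averages the four normalized symmetric
  matrices; GLRL averages the eleven features over the four directions.
  Pairs and runs are counted only when every pixel involved lies inside the
  mask (mask-aware adjacency).
* GLRL gray index i and run length j are 1-based (several features divide
  by i^2 or j^2).
* GLCM entropy uses the natural log; histogram entropy uses log2 over the
  G-bin histogram.
* "Range", "2nd STD", STD5 and STD9 are local-neighborhood statistics
  averaged over the ROI: the 3x3 max-min, and the population SD over a
  2-pixel horizontal pair, a 5-pixel plus-cross, and a full 3x3 window.
* GLGM gradients are 3x3 Sobel magnitudes; Laws masks are the nine outer
  products of L3 = [1,2,1], E3 = [-1,0,1], S3 = [-1,2,-1]; both families are
  evaluated on ROI pixels whose 3x3 window lies fully inside the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .types import ImageSlice, ROIMask

__all__ = [
    "FeatureConfig",
    "QuantizedROI",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "EXTRA_NAMES",
    "quantize",
    "histogram_features",
    "glcm_features",
    "glrl_features",
    "glgm_features",
    "laws_features",
    "extract_all",
]

FEATURE_FAMILIES: Dict[str, List[str]] = {
    "histogram": [
        "hist_mean", "hist_median", "hist_std", "hist_range",
        "hist_geometric_mean", "hist_harmonic_mean", "hist_second_std",
        "hist_std5", "hist_std9", "hist_fourth_moment", "hist_iqr",
        "hist_entropy",
    ],
    "glcm": [
        "glcm_entropy", "glcm_contrast", "glcm_correlation", "glcm_energy",
        "glcm_homogeneity",
    ],
    "glrl": [
        "glrl_sre", "glrl_lre", "glrl_gln", "glrl_rln", "glrl_rp",
        "glrl_lgre", "glrl_hgre", "glrl_srlge", "glrl_srhge", "glrl_lrlge",
        "glrl_lrhge",
    ],
    "glgm": ["glgm_mgr", "glgm_vgr", "glgm_skewness", "glgm_kurtosis"],
    "laws": [f"laws_l{k}" for k in range(1, 10)],
}

#: The 41 core feature names, in canonical order.
FEATURE_NAMES: List[str] = [n for fam in FEATURE_FAMILIES.values() for n in fam]

#: Report extras carried alongside the core 41.
EXTRA_NAMES: List[str] = ["mean_skewness", "mean_kurtosis", "mean_laws"]

_DIRECTIONS: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_L3 = np.array([1.0, 2.0, 1.0])
_E3 = np.array([-1.0, 0.0, 1.0])
_S3 = np.array([-1.0, 2.0, -1.0])
#: L1..L9 = L3L3, L3E3, L3S3, E3L3, E3E3, E3S3, S3L3, S3E3, S3S3.
LAWS_KERNELS: List[np.ndarray] = [np.outer(a, b) for a in (_L3, _E3, _S3) for b in (_L3, _E3, _S3)]

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


@dataclass
class FeatureConfig:
    n_gray_levels: int = 256
    include_extras: bool = True


@dataclass
class QuantizedROI:
    """Gray levels 0..G-1 over the image grid, valid where ``mask`` is true."""

    levels: np.ndarray
    G: int
    mask: ROIMask

    def masked(self) -> np.ndarray:
        return self.levels[self.mask.mask]


def quantize(pixels: np.ndarray, mask: ROIMask, G: int = 256) -> QuantizedROI:
    """Linear min-max binning of the masked pixels into G gray levels.

    A constant region maps to level 0.  Levels outside the mask are computed
    from the same affine map (clipped) so spatial features can address the
    full grid, but only in-mask levels are meaningful.
    """
    x = np.asarray(pixels, dtype=float)
    if mask.mask.shape != x.shape:
        raise ValueError("mask shape does not match pixels")
    if mask.n_pixels < 2:
        raise ValueError("mask must contain at least 2 pixels")
    inside = x[mask.mask]
    lo, hi = inside.min(), inside.max()
    if hi == lo:
        levels = np.zeros_like(x, dtype=np.int32)
    else:
        levels = np.clip(((x - lo) / (hi - lo) * G).astype(np.int32), 0, G - 1)
    return QuantizedROI(levels=levels, G=G, mask=mask)


def _local_sd(x: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Per-pixel population SD over a neighborhood footprint (reflect edges)."""
    f = footprint.astype(float)
    n = f.sum()
    m1 = ndimage.correlate(x, f, mode="reflect") / n
    m2 = ndimage.correlate(x * x, f, mode="reflect") / n
    return np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))


def histogram_features(roi: QuantizedROI, pixels: np.ndarray) -> Dict[str, float]:
    """First-order statistics of the masked intensities.

    Global statistics (mean, median, SD, geometric/harmonic mean, 4th central
    moment, IQR) use the raw masked intensities; entropy uses the G-bin
    quantized histogram; range/2nd-STD/STD5/STD9 are neighborhood statistics
    averaged over the masked pixels.  Geometric and harmonic means are
    computed on intensities shifted to be >= 1 whenever nonpositive values
    are present.
    """
    x = np.asarray(pixels, dtype=float)
    m = roi.mask.mask
    v = x[m]
    if v.size < 2:
        raise ValueError("need at least 2 masked pixels")

    pos = v if v.min() > 0 else v - v.min() + 1.0
    hist = np.bincount(roi.masked(), minlength=roi.G).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]

    rng_map = (
        ndimage.maximum_filter(x, size=3, mode="reflect")
        - ndimage.minimum_filter(x, size=3, mode="reflect")
    )
    pair = np.array([[1, 1]])
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    box = np.ones((3, 3))

    mu = v.mean()
    return {
        "hist_mean": float(mu),
        "hist_median": float(np.median(v)),
        "hist_std": float(v.std()),
        "hist_range": float(rng_map[m].mean()),
        "hist_geometric_mean": float(np.exp(np.mean(np.log(pos)))),
        "hist_harmonic_mean": float(pos.size / np.sum(1.0 / pos)),
        "hist_second_std": float(_local_sd(x, pair)[m].mean()),
        "hist_std5": float(_local_sd(x, cross)[m].mean()),
        "hist_std9": float(_local_sd(x, box)[m].mean()),
        "hist_fourth_moment": float(np.mean((v - mu) ** 4)),
        "hist_iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "hist_entropy": float(-np.sum(nz * np.log2(nz))),
    }


def _glcm_matrix(roi: QuantizedROI) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence probability matrix."""
    levels, m, G = roi.levels, roi.mask.mask, roi.G
    rows, cols = levels.shape
    mats = []
    for dr, dc in _DIRECTIONS:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not valid.any():
            continue
        a = levels[r0:r1, c0:c1][valid].astype(np.int64)
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid].astype(np.int64)
        counts = np.bincount(a * G + b, minlength=G * G) + np.bincount(
            b * G + a, minlength=G * G
        )
        mats.append(counts.reshape(G, G) / counts.sum())
    if not mats:
        raise ValueError("no valid adjacent in-mask pixel pair for the GLCM")
    return np.mean(mats, axis=0)


def glcm_features(roi: QuantizedROI) -> Dict[str, float]:
    """Haralick features of the direction-averaged distance-1 GLCM."""
    p = _glcm_matrix(roi)
    i, j = np.nonzero(p)
    pv = p[i, j]
    pi = p.sum(axis=1)
    idx = np.arange(roi.G, dtype=float)
    mu_i = float(np.sum(idx * pi))
    sd_i = float(np.sqrt(np.sum((idx - mu_i) ** 2 * pi)))
    # Symmetric matrix: row and column marginals coincide.
    if sd_i == 0:
        warnings.warn("constant ROI: GLCM correlation undefined", RuntimeWarning)
        corr = float("nan")
    else:
        corr = float(np.sum((i - mu_i) * (j - mu_i) * pv) / (sd_i * sd_i))
    return {
        "glcm_entropy": float(-np.sum(pv * np.log(pv))),
        "glcm_contrast": float(np.sum((i - j) ** 2 * pv)),
        "glcm_correlation": corr,
        "glcm_energy": float(np.sum(pv * pv)),
        "glcm_homogeneity": float(np.sum(pv / (1.0 + np.abs(i - j)))),
    }


def _run_lengths(line: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Values and lengths of maximal constant runs of a 1-D array."""
    if line.size == 0:
        return line, line
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return line[starts], ends - starts


def _direction_lines(levels: np.ndarray, direction: Tuple[int, int]):
    """Yield the image scan lines (as masked-level arrays) for one direction.

    ``levels`` must carry the out-of-mask sentinel already.
    """
    rows, cols = levels.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from levels
    elif (dr, dc) == (-1, 0):
        yield from levels.T
    elif (dr, dc) == (-1, 1):  # 45 degrees: anti-diagonals
        flipped = levels[:, ::-1]
        for k in range(-rows + 1, cols):
            yield np.diagonal(flipped, k)
    else:  # (-1, -1), 135 degrees: main diagonals
        for k in range(-rows + 1, cols):
            yield np.diagonal(levels, k)


def _glrl_matrix(roi: QuantizedROI, direction: Tuple[int, int]) -> np.ndarray:
    """Run-count matrix p[level, length-1] for one direction (mask-aware)."""
    sentinel = np.where(roi.mask.mask, roi.levels, -1)
    max_len = max(roi.levels.shape)
    mat = np.zeros((roi.G, max_len))
    for line in _direction_lines(sentinel, direction):
        vals, lens = _run_lengths(np.ascontiguousarray(line))
        keep = vals >= 0
        np.add.at(mat, (vals[keep], lens[keep] - 1), 1.0)
    return mat


def _glrl_direction_features(mat: np.ndarray, n_pixels: int) -> Dict[str, float]:
    gi, rj = np.nonzero(mat)
    pv = mat[gi, rj]
    i = (gi + 1).astype(float)  # 1-based gray index
    j = (rj + 1).astype(float)  # run length
    nr = pv.sum()
    if nr == 0:
        raise ValueError("no runs found in ROI")
    return {
        "glrl_sre": float(np.sum(pv / j**2) / nr),
        "glrl_lre": float(np.sum(pv * j**2) / nr),
        "glrl_gln": float(np.sum(mat.sum(axis=1) ** 2) / nr),
        "glrl_rln": float(np.sum(mat.sum(axis=0) ** 2) / nr),
        "glrl_rp": float(nr / n_pixels),
        "glrl_lgre": float(np.sum(pv / i**2) / nr),
        "glrl_hgre": float(np.sum(pv * i**2) / nr),
        "glrl_srlge": float(np.sum(pv / (i**2 * j**2)) / nr),
        "glrl_srhge": float(np.sum(pv * i**2 / j**2) / nr),
        "glrl_lrlge": float(np.sum(pv * j**2 / i**2) / nr),
        "glrl_lrhge": float(np.sum(pv * i**2 * j**2) / nr),
    }


def glrl_features(roi: QuantizedROI) -> Dict[str, float]:
    """Run-length features, averaged over the four scan directions."""
    n_pixels = roi.mask.n_pixels
    if n_pixels == 0:
        raise ValueError("empty mask")
    per_dir = [
        _glrl_direction_features(_glrl_matrix(roi, d), n_pixels) for d in _DIRECTIONS
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _interior(mask: np.ndarray) -> np.ndarray:
    """Mask pixels whose full 3x3 window lies inside the image."""
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1] = True
    return mask & inner


def glgm_features(roi: QuantizedROI, pixels: np.ndarray) -> Dict[str, float]:
    """Moments of the 3x3 Sobel gradient-magnitude distribution over the ROI."""
    x = np.asarray(pixels, dtype=float)
    sel = _interior(roi.mask.mask)
    if not sel.any():
        raise ValueError("ROI has no interior pixel with a full 3x3 neighborhood")
    gx = ndimage.correlate(x, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(x, _SOBEL_Y, mode="reflect")
    g = np.hypot(gx, gy)[sel]
    mu = g.mean()
    var = g.var()
    if var == 0:
        warnings.warn("zero gradient variance: GLGM skewness/kurtosis undefined",
                      RuntimeWarning)
        skew = kurt = float("nan")
    else:
        sd = np.sqrt(var)
        skew = float(np.mean((g - mu) ** 3) / sd**3)
        kurt = float(np.mean((g - mu) ** 4) / sd**4)
    return {
        "glgm_mgr": float(mu),
        "glgm_vgr": float(var),
        "glgm_skewness": skew,
        "glgm_kurtosis": kurt,
    }


def laws_features(roi: QuantizedROI, pixels: np.ndarray) -> Dict[str, float]:
    """Mean squared response of the nine 3x3 Laws masks over the ROI interior."""
    x = np.asarray(pixels, dtype=float)
    sel = _interior(roi.mask.mask)
    if not sel.any():
        raise ValueError("ROI has no interior pixel with a full 3x3 neighborhood")
    out: Dict[str, float] = {}
    for k, kernel in enumerate(LAWS_KERNELS, start=1):
        resp = ndimage.correlate(x, kernel, mode="reflect")
        out[f"laws_l{k}"] = float(np.mean(resp[sel] ** 2))
    return out


def _intensity_shape_extras(v: np.ndarray, laws: Dict[str, float]) -> Dict[str, float]:
    """Report extras: skewness/kurtosis of the ROI intensities; sum of Laws."""
    mu = v.mean()
    sd = v.std()
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(np.mean((v - mu) ** 3) / sd**3)
        kurt = float(np.mean((v - mu) ** 4) / sd**4)
    return {
        "mean_skewness": skew,
        "mean_kurtosis": kurt,
        "mean_laws": float(sum(laws.values())),
    }


def extract_all(
    slice_: ImageSlice, mask: ROIMask, config: FeatureConfig = FeatureConfig()
) -> Dict[str, float]:
    """Compute the 41 core features (plus extras) for one preprocessed slice.

    ``slice_.pixels`` is expected to be the normalized image and ``mask`` the
    partial-volume-corrected ROI.  Returns an ordered name -> value mapping;
    family errors propagate rather than being silently dropped.
    """
    pixels = np.asarray(slice_.pixels, dtype=float)
    roi = quantize(pixels, mask, config.n_gray_levels)
    values: Dict[str, float] = {}
    values.update(histogram_features(roi, pixels))
    values.update(glcm_features(roi))
    values.update(glrl_features(roi))
    values.update(glgm_features(roi, pixels))
    laws = laws_features(roi, pixels)
    values.update(laws)
    if config.include_extras:
        values.update(_intensity_shape_extras(pixels[mask.mask], laws))
    return values
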