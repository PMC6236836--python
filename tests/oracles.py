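"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain per-pixel Python loops, deliberately
sharing no code (and no vectorized shortcuts) with the package, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def naive_glcm_features(levels: np.ndarray, mask: np.ndarray, G: int) -> Dict[str, float]:
    rows, cols = levels.shape
    mats = []
    for dr, dc in DIRECTIONS:
        counts = np.zeros((G, G))
        n = 0
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                    a, b = levels[r, c], levels[r2, c2]
                    counts[a, b] += 1
                    counts[b, a] += 1
                    n += 2
        if n:
            mats.append(counts / n)
    p = sum(mats) / len(mats)
    mu_i = sum(i * p[i, j] for i in range(G) for j in range(G))
    mu_j = sum(j * p[i, j] for i in range(G) for j in range(G))
    sd_i = math.sqrt(sum((i - mu_i) ** 2 * p[i, j] for i in range(G) for j in range(G)))
    sd_j = math.sqrt(sum((j - mu_j) ** 2 * p[i, j] for i in range(G) for j in range(G)))
    entropy = -sum(p[i, j] * math.log(p[i, j]) for i in range(G) for j in range(G) if p[i, j] > 0)
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    energy = sum(p[i, j] ** 2 for i in range(G) for j in range(G))
    homog = sum(p[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G))
    if sd_i == 0 or sd_j == 0:
        corr = float("nan")
    else:
        corr = sum((i - mu_i) * (j - mu_j) * p[i, j] for i in range(G) for j in range(G)) / (sd_i * sd_j)
    return {
        "glcm_entropy": entropy,
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_energy": energy,
        "glcm_homogeneity": homog,
    }


def _walk_runs(levels: np.ndarray, mask: np.ndarray, d: Tuple[int, int]):
    """List (gray level, run length) of maximal in-mask runs along direction d."""
    rows, cols = levels.shape
    dr, dc = d
    runs: List[Tuple[int, int]] = []
    for r0 in range(rows):
        for c0 in range(cols):
            # start of a line: no predecessor inside the image
            if 0 <= r0 - dr < rows and 0 <= c0 - dc < cols:
                continue
            r, c = r0, c0
            cur_val, cur_len = None, 0
            while 0 <= r < rows and 0 <= c < cols:
                if mask[r, c]:
                    v = levels[r, c]
                    if v == cur_val:
                        cur_len += 1
                    else:
                        if cur_val is not None:
                            runs.append((cur_val, cur_len))
                        cur_val, cur_len = v, 1
                else:
                    if cur_val is not None:
                        runs.append((cur_val, cur_len))
                    cur_val, cur_len = None, 0
                r, c = r + dr, c + dc
            if cur_val is not None:
                runs.append((cur_val, cur_len))
    return runs


def naive_glrl_features(levels: np.ndarray, mask: np.ndarray, G: int) -> Dict[str, float]:
    n_pixels = int(mask.sum())
    per_dir = []
    for d in DIRECTIONS:
        runs = _walk_runs(levels, mask, d)
        nr = len(runs)
        sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
        by_level: Dict[int, float] = {}
        by_length: Dict[int, float] = {}
        for lev, length in runs:
            i, j = lev + 1, length
            sre += 1.0 / j**2
            lre += float(j**2)
            lgre += 1.0 / i**2
            hgre += float(i**2)
            srlge += 1.0 / (i**2 * j**2)
            srhge += i**2 / j**2
            lrlge += j**2 / i**2
            lrhge += float(i**2 * j**2)
            by_level[lev] = by_level.get(lev, 0) + 1
            by_length[length] = by_length.get(length, 0) + 1
        per_dir.append({
            "glrl_sre": sre / nr,
            "glrl_lre": lre / nr,
            "glrl_gln": sum(v**2 for v in by_level.values()) / nr,
            "glrl_rln": sum(v**2 for v in by_length.values()) / nr,
            "glrl_rp": nr / n_pixels,
            "glrl_lgre": lgre / nr,
            "glrl_hgre": hgre / nr,
            "glrl_srlge": srlge / nr,
            "glrl_srhge": srhge / nr,
            "glrl_lrlge": lrlge / nr,
            "glrl_lrhge": lrhge / nr,
        })
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


_SOBEL_X = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
_SOBEL_Y = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]


def naive_glgm_features(pixels: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    rows, cols = pixels.shape
    grads = []
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            if not mask[r, c]:
                continue
            gx = gy = 0.0
            for u in (-1, 0, 1):
                for v in (-1, 0, 1):
                    gx += _SOBEL_X[u + 1][v + 1] * pixels[r + u, c + v]
                    gy += _SOBEL_Y[u + 1][v + 1] * pixels[r + u, c + v]
            grads.append(math.hypot(gx, gy))
    g = np.array(grads)
    mu = g.mean()
    var = float(np.mean((g - mu) ** 2))
    if var == 0:
        skew = kurt = float("nan")
    else:
        skew = float(np.mean((g - mu) ** 3)) / var**1.5
        kurt = float(np.mean((g - mu) ** 4)) / var**2
    return {"glgm_mgr": float(mu), "glgm_vgr": var,
            "glgm_skewness": skew, "glgm_kurtosis": kurt}


_L3, _E3, _S3 = [1, 2, 1], [-1, 0, 1], [-1, 2, -1]
_LAWS = [[[a[u] * b[v] for v in range(3)] for u in range(3)]
         for a in (_L3, _E3, _S3) for b in (_L3, _E3, _S3)]


def naive_laws_features(pixels: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    rows, cols = pixels.shape
    out = {}
    for k, kernel in enumerate(_LAWS, start=1):
        total, n = 0.0, 0
        for r in range(1, rows - 1):
            for c in range(1, cols - 1):
                if not mask[r, c]:
                    continue
                resp = 0.0
                for u in (-1, 0, 1):
                    for v in (-1, 0, 1):
                        resp += kernel[u + 1][v + 1] * pixels[r + u, c + v]
                total += resp * resp
                n += 1
        out[f"laws_l{k}"] = total / n
    return out


def naive_benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    m = len(p_values)
    indexed = sorted(range(m), key=lambda k: p_values[k])
    q = [0.0] * m
    for rank_pos, k in enumerate(indexed):
        best = math.inf
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            best = min(best, m * p_values[indexed[later_pos]] / j)
        q[k] = min(best, 1.0)
    return q


def naive_best_threshold(values: np.ndarray, labels: np.ndarray) -> int:
    """Integer threshold in 0..255 minimizing misclassification of known labels."""
    best_t, best_err = 0, math.inf
    for t in range(256):
        err = int(np.sum((values > t) & (labels == 0))) + int(np.sum((values <= t) & (labels == 1)))
        if err < best_err:
            best_t, best_err = t, err
    return best_t
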