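"""Run-length, difference, neighbourhood-tone and statistical-feature families.

All families are mask-aware: pixel pairs, runs and neighbourhoods involving
an invalid pixel are skipped (runs are broken at invalid pixels).  Grey
levels enter value-weighted statistics 1-based, as in the co-occurrence
family.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..errors import FeatureError
from .base import EPS, QuantizedRoi

GLRLM_NAMES = ["glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln",
               "glrlm_rp", "glrlm_lgre", "glrlm_hgre"]
GLDS_STATS = ["mean", "contrast", "asm", "entropy", "idm"]
GLDS_NAMES = [f"glds_d{d}_{s}" for d in (1, 2, 4) for s in GLDS_STATS]
NGTDM_STATS = ["coarseness", "contrast", "busyness", "complexity", "strength"]
NGTDM_NAMES = [f"ngtdm_w{w}_{s}" for w in (3, 5, 7) for s in NGTDM_STATS]
SFM_STATS = ["coarseness", "contrast", "periodicity", "roughness"]
SFM_NAMES = [f"sfm_L{L}_{s}" for L in (4, 8) for s in SFM_STATS]

DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0/45/90/135 degrees


# ---------------------------------------------------------------- GLRLM

def _lines(levels: np.ndarray, valid: np.ndarray, direction):
    """1-D (levels, valid) scan lines of the image along one direction."""
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(levels.shape[0]):
            yield levels[r], valid[r]
    elif (dr, dc) == (-1, 0):
        for c in range(levels.shape[1]):
            yield levels[:, c], valid[:, c]
    elif (dr, dc) == (-1, -1):
        # runs along the main diagonal direction (down-right)
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(levels, off), np.diagonal(valid, off)
    else:  # (-1, 1): anti-diagonals
        fl, fv = np.fliplr(levels), np.fliplr(valid)
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(fl, off), np.diagonal(fv, off)


def run_lengths(levels: np.ndarray, valid: np.ndarray, direction):
    """(level, length) of every maximal run along one direction."""
    out = []
    for lev, ok in _lines(levels, valid, direction):
        key = np.where(ok, lev, -1)
        n = len(key)
        if n == 0:
            continue
        change = np.nonzero(np.diff(key))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [n]])
        for s, e in zip(starts, ends):
            if key[s] >= 0:
                out.append((int(key[s]), int(e - s)))
    return out


def _glrlm_direction(runs, n_pixels: int) -> np.ndarray:
    if not runs:
        raise FeatureError("glrlm", "no runs (all pixels invalid)")
    g = np.array([r[0] for r in runs], dtype=float) + 1.0  # 1-based level
    l = np.array([r[1] for r in runs], dtype=float)
    n_r = len(runs)
    sre = float((1.0 / l ** 2).sum() / n_r)
    lre = float((l ** 2).sum() / n_r)
    gl_counts = np.bincount(np.asarray(g, dtype=int))
    rl_counts = np.bincount(np.asarray(l, dtype=int))
    gln = float((gl_counts.astype(float) ** 2).sum() / n_r)
    rln = float((rl_counts.astype(float) ** 2).sum() / n_r)
    rp = n_r / n_pixels
    lgre = float((1.0 / g ** 2).sum() / n_r)
    hgre = float((g ** 2).sum() / n_r)
    return np.array([sre, lre, gln, rln, rp, lgre, hgre])


def glrlm_features(q: QuantizedRoi) -> np.ndarray:
    """7 run-length statistics averaged over the 4 directions."""
    n_pixels = int(q.valid.sum())
    if n_pixels == 0:
        raise FeatureError("glrlm", "all pixels invalid")
    per_dir = [_glrlm_direction(run_lengths(q.levels, q.valid, d), n_pixels)
               for d in DIRECTIONS]
    return np.mean(per_dir, axis=0)


# ---------------------------------------------------------------- GLDS

def _abs_diffs(q: QuantizedRoi, offset) -> np.ndarray:
    dr, dc = offset
    lev, val = q.levels, q.valid
    h, w = lev.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = val[r0:r1, c0:c1] & val[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return np.abs(a[ok] - b[ok]).ravel()


def glds_features(q: QuantizedRoi) -> np.ndarray:
    """5 absolute-difference statistics at displacements 1, 2, 4.

    For each displacement the difference histograms of the 4 directions are
    pooled before computing mean, contrast, angular second moment, entropy
    and inverse difference moment.
    """
    out = []
    for d in (1, 2, 4):
        counts = np.zeros(q.Ng, dtype=float)
        for dr, dc in DIRECTIONS:
            diffs = _abs_diffs(q, (dr * d, dc * d))
            if diffs.size:
                counts += np.bincount(diffs, minlength=q.Ng)
        if counts.sum() == 0:
            raise FeatureError("glds", f"no valid pairs at displacement {d}")
        p = counts / counts.sum()
        k = np.arange(q.Ng, dtype=float)
        nz = p[p > 0]
        out.extend([
            float((k * p).sum()),
            float((k ** 2 * p).sum()),
            float((p ** 2).sum()),
            float(-(nz * np.log2(nz)).sum()),
            float((p / (1.0 + k ** 2)).sum()),
        ])
    return np.array(out)


# ---------------------------------------------------------------- NGTDM

def _ngtdm_arrays(q: QuantizedRoi, window: int):
    """Amadasun s(i) and occurrence counts n(i) for one window size."""
    lev = q.levels.astype(float)
    val = q.valid.astype(float)
    h, w = lev.shape
    half = window // 2
    if h < window or w < window:
        raise FeatureError("ngtdm", f"patch smaller than {window}x{window} window")
    kern = np.ones((window, window))
    winsum = ndimage.correlate(lev * val, kern, mode="constant", cval=0.0)
    wincnt = ndimage.correlate(val, kern, mode="constant", cval=0.0)
    inner = np.zeros_like(q.valid)
    inner[half : h - half, half : w - half] = True
    centers = q.valid & inner & (wincnt - q.valid > 0.5)  # >= 1 valid neighbour
    nb_sum = winsum - lev * val
    nb_cnt = wincnt - val
    s = np.zeros(q.Ng)
    n = np.zeros(q.Ng)
    rr, cc = np.nonzero(centers)
    a_bar = nb_sum[rr, cc] / nb_cnt[rr, cc]
    g = q.levels[rr, cc]
    np.add.at(s, g, np.abs(g + 0.0 - a_bar))
    np.add.at(n, g, 1.0)
    if n.sum() == 0:
        raise FeatureError("ngtdm", "no qualifying centre pixels")
    return s, n


def _ngtdm_stats(s: np.ndarray, n: np.ndarray) -> np.ndarray:
    N = n.sum()
    p = n / N
    i = np.arange(len(p), dtype=float) + 1.0  # 1-based grey tone
    nz = p > 0
    ngp = int(nz.sum())
    coarseness = 1.0 / (EPS + float((p * s).sum()))
    if ngp > 1:
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        ii, jj = np.meshgrid(i[nz], i[nz], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / N
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p * s).sum()) / denom if denom > EPS else 0.0
        si, sj = np.meshgrid(s[nz], s[nz], indexing="ij")
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / N
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / (EPS + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


def ngtdm_features(q: QuantizedRoi) -> np.ndarray:
    """Amadasun's 5 statistics at neighbourhood sizes 3, 5 and 7."""
    out = []
    for window in (3, 5, 7):
        s, n = _ngtdm_arrays(q, window)
        out.append(_ngtdm_stats(s, n))
    return np.concatenate(out)


# ---------------------------------------------------------------- SFM

def _sfm_offsets(L: int):
    """Half-plane displacement roster with Chebyshev norm <= L."""
    out = []
    for dr in range(0, L + 1):
        for dc in range(-L, L + 1):
            if dr == 0 and dc <= 0:
                continue
            out.append((dr, dc))
    return out


def sfm_delta_stats(q: QuantizedRoi, offset):
    """(mean |diff|, mean diff^2, n pairs) for one displacement."""
    diffs = _abs_diffs(q, offset)
    if diffs.size == 0:
        return np.nan, np.nan, 0
    d = diffs.astype(float)
    return float(d.mean()), float((d ** 2).mean()), int(d.size)


def sfm_features(q: QuantizedRoi) -> np.ndarray:
    """Coarseness, contrast, periodicity, roughness at max spacing 4 and 8.

    Coarseness is the reciprocal mean dissimilarity over the displacement
    roster; contrast the RMS intensity difference at unit displacements;
    periodicity the relative depth of the dissimilarity minimum; roughness
    3 - H with H the log-log slope of dissimilarity versus axial distance.
    """
    out = []
    for L in (4, 8):
        dss, con = {}, {}
        for off in _sfm_offsets(L):
            m, c, n = sfm_delta_stats(q, off)
            if n:
                dss[off], con[off] = m, c
        if not dss:
            raise FeatureError("sfm", "no valid displacement pairs")
        vals = np.array(list(dss.values()))
        coarseness = len(vals) / (EPS + vals.sum())
        unit = [con[o] for o in ((0, 1), (1, -1), (1, 0), (1, 1)) if o in con]
        contrast = float(np.sqrt(np.mean(unit))) if unit else 0.0
        mean_dss = vals.mean()
        periodicity = float((mean_dss - vals.min()) / mean_dss) if mean_dss > EPS else 0.0
        slopes = []
        for axis_offs in ([(0, d) for d in range(1, L + 1)], [(d, 0) for d in range(1, L + 1)]):
            xs = [np.log(max(abs(o[0]), abs(o[1]))) for o in axis_offs if dss.get(o, 0) and dss[o] > 0]
            ys = [np.log(dss[o]) for o in axis_offs if dss.get(o, 0) and dss[o] > 0]
            if len(xs) >= 2:
                slopes.append(np.polyfit(xs, ys, 1)[0])
        roughness = 3.0 - (float(np.mean(slopes)) if slopes else 0.0)
        out.extend([float(coarseness), contrast, periodicity, roughness])
    return np.array(out)
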