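"""Grey-level co-occurrence features: 22 statistics x 4 offsets = 88.

Co-occurrence is accumulated symmetrically at distance 1 for the four
standard 2-D offsets (0, 45, 90, 135 degrees); any pair touching an invalid
pixel is skipped.  Value-weighted statistics (means, correlation,
autocorrelation, cluster moments, sum of squares) index grey levels 1..Ng
in the classic Haralick convention.  Statistics with a vanishing
denominator on degenerate matrices (correlation, the information measures)
return 0 so every value stays finite.
"""

from __future__ import annotations

import numpy as np

from ..errors import FeatureError
from .base import EPS, QuantizedRoi

OFFSETS = {  # degrees -> (dr, dc)
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

GLCM_STAT_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
    "autocorrelation", "cluster_shade", "cluster_prominence",
    "dissimilarity", "inverse_difference", "idn", "idmn",
    "max_probability", "sum_of_squares",
]

GLCM_NAMES = [f"glcm_{deg}deg_{s}" for deg in OFFSETS for s in GLCM_STAT_NAMES]


def cooccurrence(q: QuantizedRoi, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one (dr, dc) offset."""
    dr, dc = offset
    lev, val = q.levels, q.valid
    h, w = lev.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = val[r0:r1, c0:c1] & val[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not ok.any():
        raise FeatureError("glcm", "no valid pixel pairs for offset")
    i, j = a[ok].ravel(), b[ok].ravel()
    counts = np.bincount(i * q.Ng + j, minlength=q.Ng * q.Ng).reshape(q.Ng, q.Ng)
    counts = counts + counts.T  # symmetric
    return counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_stats(P: np.ndarray) -> np.ndarray:
    """The 22 statistics of one normalized symmetric co-occurrence matrix."""
    Ng = P.shape[0]
    lv = np.arange(1, Ng + 1, dtype=float)
    I, J = np.meshgrid(lv, lv, indexing="ij")
    px = P.sum(axis=1)
    mu = float((lv * px).sum())
    sigma2 = float(((lv - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(I - J)
    asm = float((P ** 2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    autocorr = float((I * J * P).sum())
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > EPS else 0.0
    variance = float(((I - mu) ** 2 * P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    k_sum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, P.ravel())
    k_dif = np.arange(0, Ng, dtype=float)
    p_dif = np.zeros(Ng)
    np.add.at(p_dif, diff.astype(int).ravel(), P.ravel())

    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy2(p_sum)
    entropy = _entropy2(P)
    dif_avg = float((k_dif * p_dif).sum())
    dif_var = float(((k_dif - dif_avg) ** 2 * p_dif).sum())
    dif_ent = _entropy2(p_dif)

    hx = _entropy2(px)
    pxy = np.outer(px, px)
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask] * np.log2(pxy[mask])).sum())
    nz = pxy[pxy > 0]
    hxy2 = float(-(nz * np.log2(nz)).sum())
    imc1 = (entropy - hxy1) / hx if hx > EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    shade = float(((I + J - 2 * mu) ** 3 * P).sum())
    prominence = float(((I + J - 2 * mu) ** 4 * P).sum())
    dissim = float((diff * P).sum())
    inv_diff = float((P / (1.0 + diff)).sum())
    idn = float((P / (1.0 + diff / Ng)).sum())
    idmn = float((P / (1.0 + (I - J) ** 2 / Ng ** 2)).sum())
    max_prob = float(P.max())
    sum_sq = float((I ** 2 * P).sum())

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var, sum_ent,
        entropy, dif_var, dif_ent, imc1, imc2, autocorr, shade, prominence,
        dissim, inv_diff, idn, idmn, max_prob, sum_sq,
    ])


def glcm_features(q: QuantizedRoi) -> np.ndarray:
    """88 features: GLCM_STAT_NAMES per offset, offsets kept separate."""
    if not q.valid.any():
        raise FeatureError("glcm", "all pixels invalid")
    out = [glcm_stats(cooccurrence(q, off)) for off in OFFSETS.values()]
    return np.concatenate(out)
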