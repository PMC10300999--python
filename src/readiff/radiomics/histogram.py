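"""First-order (histogram) statistics: 28 features.

Computed over in-mask pixels only.  Percentiles use numpy's linear
interpolation; entropy / uniformity / mode / peak frequency come from a
fixed 64-bin histogram between the in-mask min and max (a single bin when
the patch is constant, giving entropy 0 and uniformity 1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..errors import FeatureError
from ..preprocess import RoiImage

N_BINS = 64

HISTOGRAM_NAMES = [
    "min", "max", "range", "mean", "median", "mode", "sd", "variance",
    "mad", "rms", "cv", "skewness", "kurtosis", "energy", "entropy",
    "uniformity", "p01", "p05", "p10", "p25", "p75", "p90", "p95", "p99",
    "iqr", "range_10_90", "trimmed_mean_10", "hist_peak_frequency",
]


def histogram_features(roi: RoiImage) -> np.ndarray:
    x = roi.values.astype(float)
    if x.size == 0:
        raise FeatureError("histogram", "empty ROI")
    mn, mx = float(x.min()), float(x.max())
    mu = float(x.mean())
    sd = float(x.std(ddof=0))

    if mx > mn:
        counts, edges = np.histogram(x, bins=N_BINS, range=(mn, mx))
    else:
        counts, edges = np.array([x.size]), np.array([mn, mn])
    p = counts / x.size
    nz = p[p > 0]
    centers = (edges[:-1] + edges[1:]) / 2 if mx > mn else np.array([mn])
    mode = float(centers[int(np.argmax(counts))])
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())

    pct = np.percentile(x, [1, 5, 10, 25, 75, 90, 95, 99])
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # Fisher (excess)
    cv = sd / abs(mu) if abs(mu) > 1e-12 else 0.0

    return np.array([
        mn, mx, mx - mn, mu, float(np.median(x)), mode, sd, sd ** 2,
        float(np.mean(np.abs(x - mu))), float(np.sqrt(np.mean(x ** 2))), cv,
        skew, kurt, float(np.mean(x ** 2)), entropy, uniformity,
        *pct,
        float(pct[4] - pct[3]),          # IQR = p75 - p25
        float(pct[5] - pct[2]),          # p90 - p10
        float(stats.trim_mean(x, 0.1)),
        float(p.max()),
    ])
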