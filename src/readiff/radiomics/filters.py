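"""Gradient, Laws, fractal and transform-domain feature families.

Filter-based families operate on the patch cropped to the valid bounding
box, with any interior invalid pixels filled by the in-mask mean; summary
statistics are then restricted to valid pixels.  Filters use reflective
boundary handling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal, stats

from ..errors import FeatureError
from ..preprocess import RoiImage
from .base import crop_to_valid

GLSM_NAMES = ["glsm_mean", "glsm_sd", "glsm_skewness", "glsm_kurtosis",
              "glsm_energy", "glsm_entropy"]
LAWS_PAIRS = ["L5E5", "L5S5", "L5R5", "E5E5", "E5S5", "E5R5", "S5S5", "S5R5", "R5R5"]
LAWS_NAMES = [f"laws_{p}_{s}" for p in LAWS_PAIRS for s in ("mean", "sd")]
FRACTAL_NAMES = ["fractal_dimension", "lacunarity"]
GABOR_FREQUENCIES = (0.1, 0.25)       # cycles / pixel
GABOR_THETAS_DEG = (0, 60, 120)
GABOR_NAMES = [f"gabor_f{f}_t{t}" for f in GABOR_FREQUENCIES for t in GABOR_THETAS_DEG]
RFS_NAMES = ([f"rfs_edge_s{i}" for i in range(3)] + [f"rfs_bar_s{i}" for i in range(3)]
             + ["rfs_gaussian", "rfs_log"])
FOURIER_NAMES = ["fourier_slope", "fourier_hf_fraction"]

_LAWS_1D = {
    "L5": np.array([1.0, 4, 6, 4, 1]),
    "E5": np.array([-1.0, -2, 0, 2, 1]),
    "S5": np.array([-1.0, 0, 2, 0, -1]),
    "R5": np.array([1.0, -4, 6, -4, 1]),
}

MR8_SIGMAS = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))
MR8_ORIENTATIONS = 6
MR8_SUPPORT = 25
_GAUSS_SIGMA = 4.0


def _prepared(roi: RoiImage):
    pixels, valid = crop_to_valid(roi.pixels, roi.valid)
    if valid.sum() == 0:
        raise FeatureError("filters", "no valid pixels")
    filled = pixels.copy()
    filled[~valid] = pixels[valid].mean()
    return filled, valid


# ---------------------------------------------------------------- GLSM

def glsm_features(roi: RoiImage) -> np.ndarray:
    """First-order statistics of the Sobel gradient-magnitude map."""
    img, valid = _prepared(roi)
    gr = ndimage.sobel(img, axis=0, mode="reflect")
    gc = ndimage.sobel(img, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)[valid]
    mu, sd = float(mag.mean()), float(mag.std(ddof=0))
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew, kurt = float(stats.skew(mag)), float(stats.kurtosis(mag))
    if mag.max() > mag.min():
        counts, _ = np.histogram(mag, bins=64)
    else:
        counts = np.array([mag.size])
    p = counts / mag.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.array([mu, sd, skew, kurt, float((mag ** 2).mean()), entropy])


# ---------------------------------------------------------------- Laws

def laws_features(roi: RoiImage) -> np.ndarray:
    """Mean and SD of 9 direction-averaged Laws 5x5 texture-energy maps.

    The patch mean is removed before filtering; for asymmetric kernel pairs
    (AB vs BA) the two absolute-response maps are averaged.
    """
    img, valid = _prepared(roi)
    if min(img.shape) < 5:
        raise FeatureError("laws", "ROI smaller than the 5x5 Laws masks")
    img = img - img[valid].mean()
    out = []
    for pair in LAWS_PAIRS:
        a, b = _LAWS_1D[pair[:2]], _LAWS_1D[pair[2:]]
        k1 = np.outer(a, b)
        e = np.abs(signal.fftconvolve(img, k1, mode="same"))
        if pair[:2] != pair[2:]:
            k2 = np.outer(b, a)
            e = 0.5 * (e + np.abs(signal.fftconvolve(img, k2, mode="same")))
        v = e[valid]
        out.extend([float(v.mean()), float(v.std(ddof=0))])
    return np.array(out)


# ---------------------------------------------------------------- fractal

def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary point set over dyadic box sizes."""
    n = max(binary.shape)
    sizes = [s for s in (2, 4, 8, 16, 32, 64) if s <= n // 2]
    if not sizes or binary.sum() == 0:
        return 0.0
    counts = []
    for s in sizes:
        h = int(np.ceil(binary.shape[0] / s)) * s
        w = int(np.ceil(binary.shape[1] / s)) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: binary.shape[0], : binary.shape[1]] = binary
        blocks = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        counts.append(max(1, int(blocks.sum())))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)[0]
    return float(slope)


def gliding_box_lacunarity(binary: np.ndarray, box: int = 4) -> float:
    """Gliding-box lacunarity  E[m^2] / E[m]^2  at one box size."""
    if min(binary.shape) < box:
        return 1.0
    kern = np.ones((box, box))
    masses = signal.fftconvolve(binary.astype(float), kern, mode="valid")
    masses = np.rint(masses)
    mu = masses.mean()
    if mu == 0:
        return 1.0
    return float((masses ** 2).mean() / mu ** 2)


def fractal_features(roi: RoiImage) -> np.ndarray:
    """Box-counting dimension and lacunarity of the above-mean pixel set."""
    img, valid = _prepared(roi)
    binary = valid & (img >= img[valid].mean())
    return np.array([box_counting_dimension(binary), gliding_box_lacunarity(binary)])


# ---------------------------------------------------------------- Gabor

def _gabor_kernel(frequency: float, theta: float, sigma: float, support: int) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    env = np.exp(-(xr ** 2 + yr ** 2) / (2 * sigma ** 2))
    return env * np.exp(2j * np.pi * frequency * xr)


def gabor_features(roi: RoiImage) -> np.ndarray:
    """Mean magnitude response of 6 Gabor filters (2 frequencies x 3 angles)."""
    img, valid = _prepared(roi)
    img = img - img[valid].mean()
    out = []
    for f in GABOR_FREQUENCIES:
        sigma = 0.56 / f  # ~1 octave bandwidth
        support = min(int(2 * (3 * sigma) + 1) | 1, (min(img.shape) - 1) | 1)
        if support < 5:
            raise FeatureError("gabor", "ROI smaller than the Gabor filter support")
        for t in GABOR_THETAS_DEG:
            k = _gabor_kernel(f, np.deg2rad(t), sigma, support)
            resp = signal.fftconvolve(img, k, mode="same")
            out.append(float(np.abs(resp)[valid].mean()))
    return np.array(out)


# ---------------------------------------------------------------- MR8 / RFS

def _oriented_gaussian_derivative(sigma_x, sigma_y, theta, support, order):
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr ** 2 / (2 * sigma_x ** 2) + yr ** 2 / (2 * sigma_y ** 2)))
    if order == 1:      # edge: first derivative across the bar axis
        k = -yr / sigma_y ** 2 * g
    else:               # bar: second derivative
        k = (yr ** 2 / sigma_y ** 4 - 1.0 / sigma_y ** 2) * g
    k -= k.mean()
    norm = np.abs(k).sum()
    return k / norm if norm > 0 else k


def mr8_filter_bank(support: int = MR8_SUPPORT):
    """The 38 root filters: 6 orientations x 3 scales x {edge, bar} + G + LoG."""
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    bank = {"edge": [], "bar": []}
    thetas = [np.pi * i / MR8_ORIENTATIONS for i in range(MR8_ORIENTATIONS)]
    for sx, sy in MR8_SIGMAS:
        bank["edge"].append([_oriented_gaussian_derivative(sy, sx, t, support, 1) for t in thetas])
        bank["bar"].append([_oriented_gaussian_derivative(sy, sx, t, support, 2) for t in thetas])
    g = np.exp(-(x ** 2 + y ** 2) / (2 * _GAUSS_SIGMA ** 2))
    gauss = g / g.sum()
    r2 = x ** 2 + y ** 2
    log = (r2 / _GAUSS_SIGMA ** 4 - 2.0 / _GAUSS_SIGMA ** 2) * g
    log -= log.mean()
    log /= np.abs(log).sum()
    return bank, gauss, log


_MR8_CACHE: dict[int, tuple] = {}


def rfs_features(roi: RoiImage, support: int = MR8_SUPPORT) -> np.ndarray:
    """Mean energy of the 8 MR8 maximum-response maps.

    36 oriented edge/bar filters collapse by per-scale orientation maximum of
    the absolute response into 6 maps; the isotropic Gaussian and
    Laplacian-of-Gaussian responses complete the 8.
    """
    img, valid = _prepared(roi)
    if min(img.shape) < support:
        raise FeatureError("rfs", f"ROI smaller than the {support}x{support} MR8 support")
    img = img - img[valid].mean()
    if support not in _MR8_CACHE:
        _MR8_CACHE[support] = mr8_filter_bank(support)
    bank, gauss, log = _MR8_CACHE[support]
    out = []
    for kind in ("edge", "bar"):
        for per_scale in bank[kind]:
            resp = np.max([np.abs(signal.fftconvolve(img, k, mode="same")) for k in per_scale], axis=0)
            out.append(float((resp[valid] ** 2).mean()))
    for k in (gauss, log):
        resp = signal.fftconvolve(img, k, mode="same")
        out.append(float((resp[valid] ** 2).mean()))
    return np.array(out)


# ---------------------------------------------------------------- Fourier

def fourier_features(roi: RoiImage) -> np.ndarray:
    """Radial power-spectrum log-log slope and high-frequency power fraction.

    The high-frequency fraction is the share of (non-DC) spectral power at
    radial frequencies above half the Nyquist frequency.
    """
    img, valid = _prepared(roi)
    img = img - img[valid].mean()
    f = np.fft.fftshift(np.fft.fft2(img))
    power = np.abs(f) ** 2
    h, w = img.shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))
    fx = np.fft.fftshift(np.fft.fftfreq(w))
    rad = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    mask = rad > 0
    total = power[mask].sum()
    if total <= 0:
        raise FeatureError("fourier", "zero spectral power (constant ROI)")
    hf_fraction = float(power[mask & (rad > 0.25)].sum() / total)
    # radial binning for the slope
    nbins = 16
    edges = np.linspace(rad[mask].min(), 0.5, nbins + 1)
    idx = np.digitize(rad[mask], edges) - 1
    xs, ys = [], []
    for b in range(nbins):
        sel = idx == b
        if sel.sum() and power[mask][sel].mean() > 0:
            xs.append(np.log((edges[b] + edges[b + 1]) / 2))
            ys.append(np.log(power[mask][sel].mean()))
    slope = float(np.polyfit(xs, ys, 1)[0]) if len(xs) >= 2 else 0.0
    return np.array([slope, hf_fraction])
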