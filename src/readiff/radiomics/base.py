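"""Shared precursors for matrix-based texture families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import QuantizationError
from ..preprocess import RoiImage

EPS = 1e-12


@dataclass
class QuantizedRoi:
    """Integer grey levels in [0, Ng-1] with a validity mask."""

    levels: np.ndarray
    Ng: int
    valid: np.ndarray


def crop_to_valid(pixels: np.ndarray, valid: np.ndarray):
    """Crop to the bounding box of valid pixels (invariance to invalid padding)."""
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        return pixels[:0, :0], valid[:0, :0]
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return pixels[r0:r1, c0:c1], valid[r0:r1, c0:c1]


def quantize(roi: RoiImage, Ng: int = 32) -> QuantizedRoi:
    """Equal-width quantization of in-mask intensities into Ng levels."""
    pixels, valid = crop_to_valid(roi.pixels, roi.valid)
    vals = pixels[valid]
    if vals.size == 0:
        raise QuantizationError("no valid pixels to quantize")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise QuantizationError("constant input cannot be quantized")
    levels = np.floor((pixels - lo) / (hi - lo) * Ng).astype(np.int64)
    levels = np.clip(levels, 0, Ng - 1)
    levels[~valid] = 0  # ignored via the validity mask
    return QuantizedRoi(levels=levels, Ng=int(Ng), valid=valid)
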