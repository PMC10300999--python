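"""Full-bank extraction: one ROI in, 203 named features out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..errors import FeatureError, ReadiffError
from ..preprocess import RoiImage
from . import filters, glcm, histogram, matrices
from .base import QuantizedRoi, quantize
from .registry import FAMILY_COUNTS, FEATURE_FAMILIES, FEATURE_NAMES, config_hash

__all__ = ["FeatureVector", "extract_all", "RadiomicFeatureExtractor", "quantize", "QuantizedRoi"]


@dataclass
class FeatureVector:
    names: list[str]
    families: list[str]
    values: np.ndarray
    config_hash: str

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def extract_all(roi: RoiImage, Ng: int = 32, mr8_support: int = filters.MR8_SUPPORT) -> FeatureVector:
    """Extract the full 203-feature bank in fixed registry order.

    Matrix families run on the Ng-level equal-width quantized patch; filter
    families on the raw (cropped, mean-filled) intensities.  Family
    failures propagate as :class:`FeatureError` with the family name.
    """
    chash = config_hash({"Ng": Ng, "mr8_support": mr8_support})
    q = quantize(roi, Ng=Ng)
    blocks = [
        ("histogram", lambda: histogram.histogram_features(roi)),
        ("GLCM", lambda: glcm.glcm_features(q)),
        ("GLRLM", lambda: matrices.glrlm_features(q)),
        ("GLSM", lambda: filters.glsm_features(roi)),
        ("GLDS", lambda: matrices.glds_features(q)),
        ("NGTDM", lambda: matrices.ngtdm_features(q)),
        ("SFM", lambda: matrices.sfm_features(q)),
        ("laws", lambda: filters.laws_features(roi)),
        ("fractal", lambda: filters.fractal_features(roi)),
        ("gabor", lambda: filters.gabor_features(roi)),
        ("rfs", lambda: filters.rfs_features(roi, support=mr8_support)),
        ("fourier", lambda: filters.fourier_features(roi)),
    ]
    values = []
    for family, fn in blocks:
        try:
            block = np.asarray(fn(), dtype=float)
        except FeatureError:
            raise
        except ReadiffError as exc:
            raise FeatureError(family, str(exc)) from exc
        if block.shape != (FAMILY_COUNTS[family],):
            raise FeatureError(family, f"expected {FAMILY_COUNTS[family]} values, got {block.shape}")
        values.append(block)
    return FeatureVector(FEATURE_NAMES, FEATURE_FAMILIES, np.concatenate(values), chash)


class RadiomicFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn transformer mapping a sequence of ROIs to an (n, 203) frame.

    Stateless (``fit`` is a no-op); parameters follow sklearn conventions so
    the extractor composes with pipelines and grid search.
    """

    def __init__(self, Ng: int = 32, mr8_support: int = filters.MR8_SUPPORT):
        self.Ng = Ng
        self.mr8_support = mr8_support

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [extract_all(roi, Ng=self.Ng, mr8_support=self.mr8_support).values for roi in X]
        return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES))),
                            columns=FEATURE_NAMES)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
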