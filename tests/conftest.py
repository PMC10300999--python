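import numpy as np
import pytest

from readiff.preprocess import RoiImage
from readiff.synthetic import SyntheticConfig, generate_cohort


def make_roi(pixels, valid=None, kind="whole", view="LCC", normalized=False):
    pixels = np.asarray(pixels, dtype=float)
    if valid is None:
        valid = np.ones(pixels.shape, dtype=bool)
    return RoiImage(pixels=pixels, valid=np.asarray(valid, dtype=bool),
                    roi_kind=kind, view_tag=view,
                    bbox=(0, 0, pixels.shape[0], pixels.shape[1]),
                    normalized=normalized)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-case cohort at 128 px used by segmentation / ROI tests."""
    cfg = SyntheticConfig(n_normal=4, n_cancer=2, image_size=128, seed=7)
    cases, truths = generate_cohort(cfg)
    return cfg, cases, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_patch(rng):
    """Smooth random texture, 48x48, non-constant, fully valid."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(size=(48, 48)), 2.0)
    return make_roi(img)
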