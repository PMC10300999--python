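"""Frozen feature registry: 203 named features in fixed family order.

The registry is the stable API of the feature bank — names, families and
order never change between runs, and the extraction config hash recorded on
each FeatureVector covers quantization and filter parameters.
"""

from __future__ import annotations

import hashlib
import json

from .filters import FOURIER_NAMES, FRACTAL_NAMES, GABOR_NAMES, GLSM_NAMES, LAWS_NAMES, RFS_NAMES
from .glcm import GLCM_NAMES
from .histogram import HISTOGRAM_NAMES
from .matrices import GLDS_NAMES, GLRLM_NAMES, NGTDM_NAMES, SFM_NAMES

FAMILY_COUNTS = {
    "histogram": 28, "GLCM": 88, "GLRLM": 7, "GLSM": 6, "GLDS": 15,
    "NGTDM": 15, "SFM": 8, "laws": 18, "fractal": 2, "gabor": 6,
    "rfs": 8, "fourier": 2,
}
TOTAL_FEATURES = sum(FAMILY_COUNTS.values())  # 203

_FAMILY_NAMES = {
    "histogram": [f"hist_{n}" for n in HISTOGRAM_NAMES],
    "GLCM": GLCM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSM": GLSM_NAMES,
    "GLDS": GLDS_NAMES,
    "NGTDM": NGTDM_NAMES,
    "SFM": SFM_NAMES,
    "laws": LAWS_NAMES,
    "fractal": FRACTAL_NAMES,
    "gabor": GABOR_NAMES,
    "rfs": RFS_NAMES,
    "fourier": FOURIER_NAMES,
}

for fam, names in _FAMILY_NAMES.items():
    assert len(names) == FAMILY_COUNTS[fam], (fam, len(names))

FEATURE_NAMES: list[str] = [n for fam in FAMILY_COUNTS for n in _FAMILY_NAMES[fam]]
FEATURE_FAMILIES: list[str] = [fam for fam in FAMILY_COUNTS for _ in _FAMILY_NAMES[fam]]
assert len(FEATURE_NAMES) == TOTAL_FEATURES == len(set(FEATURE_NAMES))


def config_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]


def registry_json() -> str:
    """Machine-readable export of the feature registry."""
    return json.dumps(
        [{"index": i, "name": n, "family": f}
         for i, (n, f) in enumerate(zip(FEATURE_NAMES, FEATURE_FAMILIES))],
        indent=2,
    )
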