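"""Exception hierarchy.

Every stage raises a subclass of :class:`ReadiffError` so callers can catch
pipeline failures without catching programming errors.
"""


class ReadiffError(Exception):
    """Base class for all readiff failures."""


class ConfigurationError(ReadiffError):
    """Invalid configuration values (sizes, counts, ranges)."""


class InputError(ReadiffError):
    """Malformed or inconsistent input data."""


class SegmentationError(ReadiffError):
    """Breast segmentation could not produce a usable mask."""


class RoiError(ReadiffError):
    """ROI delineation failed (e.g. mask too small for a square)."""


class NormalizationError(ReadiffError):
    """Z-score normalization impossible (zero variance)."""


class QuantizationError(ReadiffError):
    """Grey-level quantization impossible (constant input)."""


class FeatureError(ReadiffError):
    """A radiomic feature family failed on degenerate input."""

    def __init__(self, family: str, message: str):
        self.family = family
        super().__init__(f"[{family}] {message}")


class IncompletePanelError(InputError):
    """A reader x case grid has missing responses."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"incomplete reader panel; missing (reader, case) pairs: {self.missing[:10]}"
            + ("..." if len(self.missing) > 10 else "")
        )
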