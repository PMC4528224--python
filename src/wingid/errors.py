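"""Exception hierarchy for the wingid pipeline."""


class WingidError(Exception):
    """Base class for all wingid-specific failures."""


class ImageError(WingidError):
    """Raster input that cannot be read or has an unsupported layout."""


class NoObjectError(WingidError):
    """Binarization or cleaning found no usable foreground object."""


class OutlineError(WingidError):
    """Contour extraction produced no valid closed single-pixel outline."""


class ChainCodeError(WingidError):
    """Pixel sequence cannot be encoded as a closed 8-directional chain."""


class DegenerateOutlineError(WingidError):
    """First-harmonic magnitude too small to normalize (point-like outline)."""


class ConfigError(WingidError):
    """Malformed run configuration."""


class ModelError(WingidError):
    """Classifier persistence/compatibility problem (e.g. feature-length mismatch)."""
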