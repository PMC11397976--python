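"""Exception hierarchy.

Fatal acquisition problems (missing fluorescence frame, mismatched
dimensions, unreadable files) are distinct from configuration mistakes so a
batch run can skip a bad sample folder while still aborting on a bad config.
"""


class CanopyScopeError(Exception):
    """Base class for all canopyscope errors."""


class ConfigurationError(CanopyScopeError):
    """Invalid configuration value (bounds, window, scale, colormap...)."""


class ImageFormatError(CanopyScopeError):
    """File is not an 8-bit single-channel grayscale image."""


class MissingBandError(CanopyScopeError):
    """A required waveband file/image is absent."""


class DimensionMismatchError(CanopyScopeError):
    """Waveband frames in one sample do not share identical dimensions."""


class NotBimodalError(CanopyScopeError):
    """Automatic peak search found fewer than two qualifying histogram modes."""


class NoSignalError(CanopyScopeError):
    """Gray-card image is entirely dark; exposure cannot be scaled from zero."""
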