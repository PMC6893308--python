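"""Exception hierarchy shared across the pipeline stages."""


class FtirSwaError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(FtirSwaError):
    """Malformed input table or JCAMP-DX block."""


class GridMismatchError(FtirSwaError):
    """Spectra that must share a wavenumber grid do not."""


class CoverageError(FtirSwaError):
    """A required wavenumber window is not covered by the grid."""


class ExtrapolationError(FtirSwaError):
    """Resampling target lies outside the source grid span."""


class ReplicateCountError(FtirSwaError):
    """Fewer replicates than the statistical procedure requires."""


class DegenerateSpectrumError(FtirSwaError):
    """All-zero (or otherwise unusable) absorbance where a norm is needed."""


class DegenerateVarianceError(FtirSwaError):
    """Zero total variance where a decomposition is requested."""


class UniquenessError(FtirSwaError):
    """Duplicate (condition, replicate) keys in one input table."""


class ConfigError(FtirSwaError):
    """Invalid or contradictory configuration."""
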