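"""Exception hierarchy shared across the package."""


class MilkscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MilkscreenError):
    """A file does not conform to the expected tabular dialect."""


class ParseError(MilkscreenError):
    """A cell in a spectra file could not be parsed as a number."""


class ConfigError(MilkscreenError):
    """Invalid configuration value."""


class DataError(MilkscreenError):
    """Input data violates a precondition (missing/non-finite fields)."""


class ShapeError(MilkscreenError):
    """Dimension mismatch between data and fitted parameters."""


class FitError(MilkscreenError):
    """A model cannot be fitted on the given data."""


class SelectionError(MilkscreenError):
    """A wavenumber band selection retains no grid points."""


class PreprocessingError(MilkscreenError):
    """A preprocessing step received degenerate input."""


class StateError(MilkscreenError):
    """An operation was called on an unfitted model."""


class IntegrityError(MilkscreenError):
    """A model archive is corrupt or truncated."""


class ModelVersionError(MilkscreenError):
    """Model archive format version does not match this code."""
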