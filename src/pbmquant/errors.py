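"""Exception hierarchy shared by all pbmquant modules.

``PbmQuantError`` is the common base so callers can catch everything the
package raises deliberately; the CLI maps ``ValidationError`` (and
subclasses) to exit code 1 and anything else to 2.
"""


class PbmQuantError(Exception):
    """Base class for all errors raised by pbmquant."""


class ValidationError(PbmQuantError, ValueError):
    """Input data violates a documented contract."""


class FormatError(ValidationError):
    """A file is readable but not in the expected format (e.g. missing column)."""


class ParameterError(ValidationError):
    """A parameter is outside its documented bounds."""


class InsufficientDataError(ValidationError):
    """Too few points/lags/samples for the requested computation."""


class FitError(InsufficientDataError):
    """A regression cannot be performed on the requested range."""


class GenerationError(PbmQuantError, RuntimeError):
    """A synthetic scene could not be realised (e.g. non-overlap unsatisfiable)."""


class ConfigError(ValidationError):
    """A run configuration is missing a block or contains unknown keys."""
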