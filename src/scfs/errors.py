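"""Exception hierarchy for the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
any other ScfsError -> 4.
"""


class ScfsError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ScfsError):
    """Invalid configuration, unknown preset name, bad parameter value."""


class DataError(ScfsError):
    """Problems with input data (files or in-memory records)."""


class FormatError(DataError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(DataError):
    """An in-memory object violates a structural invariant."""


class InsufficientDataError(DataError):
    """A record is too short for the requested operation."""


class DomainError(ScfsError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FitError(ScfsError):
    """A model fit did not converge or the model clearly mismatches the data."""
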