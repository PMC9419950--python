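"""Exception hierarchy shared across the pipeline.

Two broad classes matter to callers: :class:`ValidationError` for bad
arguments or configuration (CLI exit code 2) and :class:`DataError` for
inputs that are well-formed requests on data that cannot support them
(CLI exit code 3).
"""


class CrisprAmpError(Exception):
    """Base class for all package errors."""


class ValidationError(CrisprAmpError, ValueError):
    """Invalid argument, configuration value, or sequence alphabet."""


class AlphabetError(ValidationError):
    """Sequence contains symbols outside A/C/G/T."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the requested operation (e.g. a
    homopolymer cannot be scrambled into a distinct permutation)."""


class ConfigError(ValidationError):
    """Inconsistent run configuration."""


class DataError(CrisprAmpError):
    """Well-formed request on data that cannot support it."""


class ConsistencyError(DataError):
    """Tables that should join or agree do not."""


class NormalizationError(DataError):
    """A gel series lacks a usable time-zero reference lane."""


class UndefinedStatisticError(DataError):
    """A frequency or specificity is undefined (zero denominator)."""
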