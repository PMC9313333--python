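"""Exception hierarchy.

The CLI maps :class:`DataError` to exit code 2 and :class:`ConfigError`
to exit code 3; everything else is a bug.
"""


class EmdHrvError(Exception):
    """Base class for all package errors."""


class DataError(EmdHrvError):
    """Input data violates a precondition (too short, missing records, ...)."""


class ParseError(DataError):
    """A text record could not be parsed; carries file/line context."""


class FormatError(DataError):
    """A structured file (CSV) is missing required columns or is inconsistent."""


class ParameterError(EmdHrvError):
    """A parameter or configuration value is invalid."""


class ConfigError(ParameterError):
    """A pipeline configuration file is invalid."""


class DecompositionError(DataError):
    """EMD could not extract the required number of intrinsic mode functions."""
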