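"""Exception types shared across the package."""


class JunctionQCError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(JunctionQCError, ValueError):
    """A simulation or analysis configuration violates an invariant."""


class FormatError(JunctionQCError, ValueError):
    """A file does not conform to its declared format.

    Parameters
    ----------
    message : description of the violation.
    line : 1-based line number in the offending file, if known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class CoordinateError(JunctionQCError, ValueError):
    """A coordinate falls outside the object it refers to."""


class UndefinedStatisticError(JunctionQCError, ValueError):
    """A summary statistic is requested on input for which it is undefined."""
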