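"""Exception types shared across the package."""


class PopdiffError(Exception):
    """Base class for all popdiff errors."""


class InvalidInputError(PopdiffError, ValueError):
    """A computation was handed input violating its preconditions."""


class ConfigurationError(PopdiffError, ValueError):
    """A run was configured inconsistently (missing rule, unknown key, ...)."""


class ParseError(PopdiffError, ValueError):
    """An interchange file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
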