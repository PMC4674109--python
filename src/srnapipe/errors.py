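"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError/DataError -> 3.
"""


class SrnaPipeError(Exception):
    """Base class for all package errors."""


class ParameterError(SrnaPipeError, ValueError):
    """A function argument violates its precondition."""


class FormatError(SrnaPipeError, ValueError):
    """Malformed input file; message carries file and position."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}: "
            if line is not None:
                loc = f"{path}:{line}: "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class ConfigError(SrnaPipeError, ValueError):
    """Invalid run configuration; message names the offending field(s)."""


class DataError(SrnaPipeError, ValueError):
    """Semantically invalid data encountered mid-pipeline."""
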