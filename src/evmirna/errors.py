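"""Exception hierarchy mapped onto CLI exit codes.

Exit codes: 0 success, 2 configuration/specification error, 3 data-format
error, 4 statistical precondition error.
"""


class EvmirnaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(EvmirnaError):
    """Invalid run configuration or simulation specification."""

    exit_code = 2


class SpecificationError(ConfigurationError):
    """A simulation design/effect specification violates its invariants."""


class DataFormatError(EvmirnaError):
    """An input file does not conform to its declared format."""

    exit_code = 3

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class AnalysisError(EvmirnaError):
    """A statistical precondition is violated (rank, df, empty subsets...)."""

    exit_code = 4
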