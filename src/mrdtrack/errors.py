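"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: SchemaError → 2, InvalidParameterError → 3,
numerical errors (OutOfRangeError, UndefinedStatisticError, ConfoundingError,
MissingDataError) → 4.
"""


class MRDTrackError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MRDTrackError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class MissingDataError(MRDTrackError):
    """A required input (counts, mass, measurements) is absent."""


class SchemaError(MRDTrackError):
    """A tabular input does not match its documented schema."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        self.line = line
        self.column = column
        super().__init__(message)


class OutOfRangeError(MRDTrackError):
    """A numerical solve has no solution on the data range."""


class UndefinedStatisticError(MRDTrackError):
    """A statistic is undefined for the given input (e.g. OPA with zero nucleotides)."""


class ConfoundingError(MRDTrackError):
    """A design factor is confounded and its variance component is not estimable."""

    def __init__(self, factor: str):
        self.factor = factor
        super().__init__(f"factor {factor!r} is confounded with the abundance stratum")
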