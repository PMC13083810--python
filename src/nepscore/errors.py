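"""Exception hierarchy for nepscore.

Exit-code mapping in the CLI: DataError -> 2 (bad input data),
UsageError/ParameterError -> click usage handling, everything else -> 1.
"""


class NepscoreError(Exception):
    """Base class for all package errors."""


class DataError(NepscoreError):
    """Invalid input data (schema, values, emptiness)."""


class SchemaError(DataError):
    """A required column is missing or misnamed."""


class ValidationError(DataError):
    """Row-level value failure; carries the offending row indices."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EmptyInputError(DataError):
    """The input contains no cells."""


class ParameterError(NepscoreError):
    """A parameter violates its contract (k >= n, alpha out of range, ...)."""


class DegenerateGeometryError(NepscoreError):
    """Too few or collinear points for a triangulation."""


class PackingError(NepscoreError):
    """A hard-core / circle-packing target could not be met within budget."""
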