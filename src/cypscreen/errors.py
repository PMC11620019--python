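"""Exception hierarchy.

All package errors derive from :class:`CypscreenError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from runtime failures
(exit code 3).
"""


class CypscreenError(Exception):
    """Base class for all cypscreen errors."""


class SchemaError(CypscreenError):
    """An input table is missing a required column or has a malformed header."""


class KBValidationError(CypscreenError):
    """A knowledge-base row failed validation (row number and value included)."""


class ConfigurationError(CypscreenError):
    """A required configuration item (formulary, analyte mapping, period) is
    missing or inconsistent."""


class QueryParseError(CypscreenError):
    """Co-occurrence query text does not match the dialect grammar."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class GenerationError(CypscreenError):
    """The synthetic-EHR generator was given an infeasible specification."""


class DashboardError(CypscreenError):
    """A dashboard aggregation received inconsistent inputs (e.g. a hit for a
    patient absent from the patient table, or an unknown medical unit)."""
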