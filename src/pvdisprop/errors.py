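"""Exception hierarchy for the pvdisprop pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class PvdispropError(Exception):
    """Base class for all package errors."""


class ConfigError(PvdispropError):
    """Invalid configuration (simulator or run config)."""


class DataError(PvdispropError):
    """Base class for problems with input data."""


class SchemaError(DataError):
    """A required column is missing or a table is malformed."""


class ReferentialError(DataError):
    """A foreign key does not resolve; carries the offending report ids."""

    def __init__(self, message: str, report_ids=()):
        super().__init__(message)
        self.report_ids = list(report_ids)


class DefinitionError(PvdispropError):
    """An exposure definition resolves to an empty drug set."""


class UndefinedEstimateError(PvdispropError):
    """A disproportionality estimate is undefined and correction is disabled."""
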