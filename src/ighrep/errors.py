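"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: config errors -> 2, data errors -> 3,
model errors -> 4.
"""


class IghrepError(Exception):
    """Base class for all errors raised by ighrep."""


class ConfigError(IghrepError):
    """Invalid configuration (bad parameter value, unknown family name, ...)."""


class DataError(IghrepError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column is missing from an input table."""


class RowValidationError(DataError):
    """A row failed type or invariant validation; the message names the row."""


class UnknownIsotypeError(DataError):
    """A constant-region call does not map to one of the 8 IGH subclasses."""


class ContractError(DataError):
    """An operation precondition was violated (mixed participants, coverage, ...)."""


class EmptyRepertoireError(DataError):
    """A participant has no clone records, so per-repertoire measures are undefined."""


class ModelError(IghrepError):
    """Model fitting failed (rank deficiency, missing reference level, ...)."""
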