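"""Exception hierarchy shared across the package."""


class MvcotrainError(Exception):
    """Base class for all package errors."""


class SchemaError(MvcotrainError):
    """A table or file does not have the expected columns/structure."""


class ParseError(MvcotrainError):
    """A cell could not be parsed; message names the offending row/column."""


class ValidationError(MvcotrainError):
    """A value is outside its permitted domain."""


class ConfigurationError(MvcotrainError):
    """An experiment / co-training configuration is inconsistent."""


class StratificationError(MvcotrainError):
    """A stratified split is impossible (e.g. a class with < 2 rows)."""


class ImputationError(MvcotrainError):
    """Imputation cannot produce a value (e.g. fully missing column)."""
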