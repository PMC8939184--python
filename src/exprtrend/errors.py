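"""Exception hierarchy shared across the pipeline stages."""


class ExprTrendError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExprTrendError):
    """A parameter or configuration value is invalid or inconsistent."""


class FormatError(ExprTrendError):
    """An input file violates its declared format."""


class DataError(ExprTrendError):
    """Data values are structurally valid but unusable for the operation."""
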