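"""Exception types shared across the package."""


class EndoqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EndoqtlError):
    """Invalid configuration value or combination of values."""


class ParseError(EndoqtlError):
    """Malformed input file; message names the offending file/line."""


class AxisMismatchError(EndoqtlError):
    """Matrices or tables that must share axes do not."""


class UndefinedLdError(EndoqtlError):
    """LD requested between variants where correlation is undefined
    (zero variance or too few complete pairs) — distinct from r = 0."""


class UntestableError(EndoqtlError):
    """A test whose design cannot be fitted (separation, empty cells);
    the outcome is 'untestable', never a p-value."""


class DependencyError(EndoqtlError):
    """A pipeline stage was requested before its upstream outputs exist."""
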