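"""Exception types shared across the package."""


class CrcMetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(CrcMetricsError):
    """An input value or table violates a documented precondition."""


class ConfigurationError(CrcMetricsError):
    """A configuration object holds an inadmissible value."""


class InsufficientDataError(CrcMetricsError):
    """Too few observations to apply the requested procedure."""
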