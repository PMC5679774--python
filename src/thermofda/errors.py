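"""Exception hierarchy shared across the package."""


class ThermoFDAError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThermoFDAError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(ThermoFDAError, ValueError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(ThermoFDAError, ValueError):
    """Input data violate a content constraint (duplicates, bad labels, ...)."""


class RangeError(ThermoFDAError, ValueError):
    """A temperature/grid range request falls outside the available data."""


class ParameterError(ThermoFDAError, ValueError):
    """An operation was called with inconsistent numerical parameters."""
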