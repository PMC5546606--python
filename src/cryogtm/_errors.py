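"""Structured exceptions shared across the package."""


class CryoGtmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CryoGtmError, ValueError):
    """An invalid configuration value (grid shape, basis width, box size...)."""


class DataError(CryoGtmError, ValueError):
    """Inconsistent or degenerate input data (count mismatches, NaNs, ...)."""
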