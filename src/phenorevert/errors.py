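"""Exception types shared across the package."""


class PhenorevertError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenorevertError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(PhenorevertError, ValueError):
    """Input data violate a precondition of the requested operation."""
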