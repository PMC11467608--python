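"""Exception hierarchy shared across the package."""


class OcochewError(Exception):
    """Base class for all package errors."""


class FormatError(OcochewError):
    """A file does not conform to the expected on-disk layout."""


class DataError(OcochewError):
    """Input data violates an invariant (non-monotone time, overlap, NaNs...)."""


class ConfigError(OcochewError):
    """A configuration value is out of its valid range."""
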