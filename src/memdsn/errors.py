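"""Exception hierarchy shared across the package."""


class MemdsnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MemdsnError):
    """A file does not follow the expected on-disk format."""


class ValidationError(MemdsnError):
    """Parsed content violates a domain invariant (bad residue, bad label...)."""


class ConfigurationError(MemdsnError):
    """A configuration value is out of range or inconsistent."""
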