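"""Exception hierarchy shared by all immunosite modules."""


class ImmunositeError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunositeError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ImmunositeError):
    """Parsed data violates a domain invariant."""


class ConfigurationError(ImmunositeError):
    """A configuration value is inconsistent or unusable."""
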