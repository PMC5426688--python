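"""Exception hierarchy shared across the package."""


class MetadagError(Exception):
    """Base class for all package errors."""


class FormatError(MetadagError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(MetadagError):
    """Parsed data violates a domain invariant."""
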