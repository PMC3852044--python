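"""Exception hierarchy used across the package."""


class OrthodiffError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OrthodiffError):
    """A file could not be parsed; the message names the offending line/row."""


class ValidationError(OrthodiffError):
    """Inputs violate a documented contract."""


class PathExplosionError(OrthodiffError):
    """Simple-path enumeration exceeded the configured cap."""
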