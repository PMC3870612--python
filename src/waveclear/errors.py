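"""Exception hierarchy.

Validation-type errors map to CLI exit code 2, I/O and format errors to 3.
"""


class WaveclearError(Exception):
    """Base class for all package errors."""


class ValidationError(WaveclearError, ValueError):
    """Invalid parameter, configuration or input value."""


class ConfigurationError(ValidationError):
    """Unsupported basis or inconsistent algorithm constants."""


class InputShapeError(ValidationError):
    """Image or subband dimensions violate a structural precondition."""


class DegenerateRegionError(ValidationError):
    """A metric's denominator vanishes (constant region, zero contrast)."""


class ImageIOError(WaveclearError, OSError):
    """Unreadable file, unsupported format or lossy output request."""
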