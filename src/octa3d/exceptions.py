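"""Exception hierarchy for octa3d.

All octa3d errors derive from :class:`OctaError` so callers can catch the
whole family; each subclass also derives from the closest builtin so that
idiomatic ``except ValueError`` style code keeps working.
"""


class OctaError(Exception):
    """Base class for all octa3d errors."""


class ValidationError(OctaError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(OctaError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(OctaError, IOError):
    """A file on disk cannot be interpreted in a supported format."""


class RegistrationError(OctaError, RuntimeError):
    """Feature-based registration failed for one of the input images."""


class DegenerateInputError(OctaError, ValueError):
    """The input is degenerate for the requested operation (e.g. a constant
    image offered for thresholding, or an empty skeleton)."""
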