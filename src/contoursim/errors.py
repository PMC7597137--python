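"""Exception hierarchy for contoursim.

All exceptions derive from :class:`ContourError`, itself a ``ValueError``,
so callers can catch either the specific condition or anything raised by
this package's validation layer.
"""


class ContourError(ValueError):
    """Base class for all contoursim errors."""


class InvalidSpecError(ContourError):
    """A synthetic-shape specification is invalid (e.g. too few nodes)."""


class MaskError(ContourError):
    """A binary mask cannot be traced."""


class NoShapeError(MaskError):
    """Mask contains no foreground pixels."""


class AmbiguousMaskError(MaskError):
    """Mask contains more than one connected foreground component."""


class TooSmallError(MaskError):
    """Foreground component has fewer than 3 boundary pixels."""


class ZeroBranchError(ContourError):
    """A star network has a zero-length branch (duplicate contour points)."""


class OpenContourError(ContourError):
    """An operation requiring a closed (cyclic) contour got an open one."""


class ProfileLengthError(ContourError):
    """Profile length is incompatible with the window size; resample first."""


class ConstantProfileError(ContourError):
    """A correlation is undefined because a profile is constant."""


class ParseError(ContourError):
    """A contour or profile file could not be parsed."""


class ConfigError(ContourError):
    """A run configuration is inconsistent."""
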