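"""Exception hierarchy.

All readers raise :class:`FormatError` on malformed input rather than
silently coercing; generators and analysis stages raise
:class:`InvalidParameterError` on out-of-contract arguments.
"""


class SpatproxError(Exception):
    """Base class for all package errors."""


class FormatError(SpatproxError):
    """A file did not conform to its expected on-disk format."""


class InvalidParameterError(SpatproxError, ValueError):
    """A parameter violated an operation's precondition."""
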