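"""Exception hierarchy shared across the package."""


class JointcodesError(Exception):
    """Base class for all package-specific errors."""


class ParseError(JointcodesError):
    """A file could not be tokenized/parsed; the message names the line."""


class StructureError(JointcodesError):
    """Parsed content violates a structural contract (e.g. frame gaps)."""


class ValidationError(JointcodesError):
    """An in-memory object violates its invariants (shapes, finiteness)."""


class GeometryError(JointcodesError):
    """A geometric construction is degenerate (collinear points, zero axis)."""
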